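"""Pedigree-net construction, traversal and queries."""

import io
import random

import pytest

from pednet import (
    ParentChildRecord,
    PedigreeStructureError,
    UnknownLineError,
    assign_generations,
    build_net,
    classify_lines,
)

from conftest import random_net_records


class TestBuildNet:
    def test_single_record_creates_parents_as_founders(self, quench_net):
        assert sorted(quench_net.lines) == ["Drum", "Quench", "Sebastian"]
        assert quench_net.n_edges() == 2
        assert quench_net.parents("Quench") == ("Sebastian", "Drum")
        assert quench_net.is_founder("Sebastian")

    def test_mutual_parentage_is_a_cycle_error(self):
        with pytest.raises(PedigreeStructureError, match="cycle"):
            build_net([ParentChildRecord("A", "B"), ParentChildRecord("B", "A")])

    def test_selfing_fills_both_roles(self):
        net = build_net([ParentChildRecord("S", "A", "A")])
        assert net.parents("S") == ("A", "A")
        assert net.progeny("A") == {"S"}
        assert net.usage_count("A") == 1

    def test_conflicting_duplicate_definition_rejected(self):
        with pytest.raises(PedigreeStructureError, match="defined twice"):
            build_net(
                [ParentChildRecord("X", "A", "B"), ParentChildRecord("X", "A", "C")]
            )

    def test_deep_self_ancestry_rejected(self):
        with pytest.raises(PedigreeStructureError, match="cycle"):
            build_net(
                [
                    ParentChildRecord("B", "A"),
                    ParentChildRecord("C", "B"),
                    ParentChildRecord("A", "C"),
                ]
            )


class TestTraversal:
    def test_parents_progeny_ancestors_on_worked_net(self, quench_net):
        assert quench_net.ancestors("Quench", 1) == {"Sebastian", "Drum"}
        assert quench_net.ancestors("Quench", 0) == set()
        assert quench_net.descendants("Sebastian", 1) == {"Quench"}
        assert quench_net.progeny("Sebastian") == {"Quench"}
        assert quench_net.descendants("Quench") == set()

    def test_unknown_line_raises(self, quench_net):
        for op in (quench_net.parents, quench_net.progeny, quench_net.ancestors):
            with pytest.raises(UnknownLineError):
                op("nope")

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(42)
        for _ in range(20):
            net = build_net(random_net_records(rng, 5, rng.randint(5, 45)))
            parents = {line: set(net.parents(line)) for line in net.lines}

            def closure(start, step):
                out, frontier = set(), {start}
                while frontier:
                    frontier = {n for f in frontier for n in step(f)} - out
                    out |= frontier
                return out - {start}

            for line in net.lines:
                assert net.ancestors(line) == closure(line, lambda n: parents[n])
                assert net.descendants(line) == closure(line, net.progeny)
                assert line not in net.ancestors(line)  # acyclicity

    def test_bounded_depth_equals_bfs_prefix(self, diamond_net):
        assert diamond_net.ancestors("D", 1) == {"C", "E"}
        assert diamond_net.ancestors("D", 2) == {"C", "E", "A", "B"}
        assert diamond_net.ancestors("D") == {"C", "E", "A", "B"}


class TestLocalView:
    def test_one_generation_window(self, diamond_net):
        sub = diamond_net.local_view("C", 1, 1)
        assert set(sub.lines) == {"A", "B", "C", "D"}
        assert sub.n_edges() == 3  # A->C, B->C, C->D (E outside window)

    def test_zero_window_is_single_line(self, diamond_net):
        sub = diamond_net.local_view("C", 0, 0)
        assert sub.lines == ["C"] and sub.n_edges() == 0

    def test_quench_back_one(self, quench_net):
        sub = quench_net.local_view("Quench", 1, 0)
        assert set(sub.lines) == {"Quench", "Sebastian", "Drum"}


class TestGenerations:
    def test_longest_path_layering_on_left_deep_chain(self):
        net = build_net(
            [
                ParentChildRecord("A/B", "A", "B"),
                ParentChildRecord("A/B//C", "A/B", "C"),
                ParentChildRecord("X", "A/B//C", "D"),
            ]
        )
        layers = assign_generations(net)
        assert layers == {
            "A": 0, "B": 0, "C": 0, "D": 0, "A/B": 1, "A/B//C": 2, "X": 3,
        }

    def test_founder_into_deep_cross_sits_below_deepest_parent(self):
        records = [ParentChildRecord("X0", "A", "B")]
        for i in range(1, 6):
            records.append(ParentChildRecord(f"X{i}", f"X{i-1}", "B"))
        records.append(ParentChildRecord("Y", "F", "X5"))
        layers = assign_generations(build_net(records))
        assert layers["F"] == 0 and layers["X5"] == 6 and layers["Y"] == 7

    def test_invariant_and_idempotence_on_random_nets(self):
        rng = random.Random(3)
        for _ in range(10):
            net = build_net(random_net_records(rng, 6, 40))
            layers = assign_generations(net)
            for parent, child, _ in net.edges():
                assert layers[child] >= layers[parent] + 1
            assert assign_generations(net) == layers


class TestUsageAndRoles:
    def test_usage_counts_distinct_children(self):
        net = build_net(
            [
                ParentChildRecord("S", "A", "A"),
                ParentChildRecord("T", "A", "B"),
                ParentChildRecord("U", "A", "B"),
            ]
        )
        assert net.usage_count("A") == 3  # selfing counted once per child
        assert net.usage_count("S") == 0
        for line in net.lines:
            assert net.usage_count(line) == len(net.progeny(line))

    def test_classification_partition(self):
        rng = random.Random(17)
        net = build_net(random_net_records(rng, 6, 60))
        roles = classify_lines(net, principal_threshold=5)
        assert set(roles) == set(net.lines)
        for line, role in roles.items():
            usage = net.usage_count(line)
            if usage == 0:
                assert role == "terminal"
            elif usage >= 5:
                assert role == "principal"
            elif net.is_founder(line):
                assert role == "flanking"
            else:
                assert role == "intermediate"

    def test_threshold_boundaries(self):
        records = [ParentChildRecord(f"X{i}", "P", "Q") for i in range(5)]
        records.append(ParentChildRecord("Y", "Q", "X0"))
        roles = classify_lines(build_net(records), principal_threshold=5)
        assert roles["P"] == "principal"  # used 5 times
        assert roles["Q"] == "principal"  # 6 uses
        assert roles["X1"] == "terminal"
        assert roles["X0"] == "intermediate"  # non-founder, used once


class TestQueries:
    def test_wildcard_search(self, quench_net):
        assert quench_net.search_lines("Que*") == ["Quench"]
        assert quench_net.search_lines("q?ench") == ["Quench"]
        assert quench_net.search_lines("*") == sorted(quench_net.lines)
        assert quench_net.search_lines("zzz*") == []

    def test_selection_edges_matches_path_oracle(self):
        rng = random.Random(23)
        net = build_net(random_net_records(rng, 5, 30))
        for line in list(net.lines)[:10]:
            anc = net.ancestors(line)
            desc = net.descendants(line)
            oracle = set()
            for p, c, role in net.edges():
                on_anc_path = p in anc and (c in anc or c == line)
                on_desc_path = (p == line or p in desc) and c in desc
                if on_anc_path or on_desc_path:
                    oracle.add((p, c, role))
            assert net.selection_edges(line) == oracle

    def test_selection_on_quench_keeps_both_parent_edges(self, quench_net):
        assert quench_net.selection_edges("Quench") == {
            ("Sebastian", "Quench", "parent_1"),
            ("Drum", "Quench", "parent_2"),
        }

    def test_selection_on_isolated_founder_is_empty(self):
        net = build_net([ParentChildRecord("Lone")])
        assert net.selection_edges("Lone") == set()

    def test_degree_summary(self, quench_net):
        assert quench_net.degree_summary("Quench") == (2, 0, [])
        assert quench_net.degree_summary("Sebastian") == (0, 1, ["Quench"])
        selfed = build_net([ParentChildRecord("S", "A", "A")])
        assert selfed.degree_summary("A") == (0, 2, ["S"])

    def test_export_selection_preserves_order_and_duplicates(self, quench_net):
        buf = io.StringIO()
        n = quench_net.export_selection(["Quench", "Sebastian", "Quench"], buf)
        assert n == 3
        assert buf.getvalue().splitlines() == ["Quench", "Sebastian", "Quench"]
        with pytest.raises(UnknownLineError, match="nope"):
            quench_net.export_selection(["nope"], io.StringIO())
        empty = io.StringIO()
        assert quench_net.export_selection([], empty) == 0 and empty.getvalue() == ""
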