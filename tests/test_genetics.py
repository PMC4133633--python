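"""Genotype IO, allele-sharing similarity, Mendelian checks, matching."""

import io
import itertools

import numpy as np
import pytest

from pednet import (
    GenotypeFormatError,
    GenotypeMatrix,
    ParentChildRecord,
    PednetError,
    UnknownLineError,
    build_net,
    check_mendelian,
    infer_second_parent,
    locus_similarity,
    match_genotype,
    pairwise_similarity,
    read_genotypes,
    similarity_matrix,
    threshold_similar,
    trio_consistent,
    write_genotypes,
)


def toy_matrix():
    return GenotypeMatrix(
        ["a", "b"],
        ["m1", "m2", "m3"],
        [["AA", "AG", "GG"], ["AA", "GA", "-"]],
    )


class TestGenotypeIO:
    def test_read_toy_file(self):
        text = "line\tm1\tm2\tm3\n" "a\tAA\tAG\tGG\n" "b\tAA\tGA\t-\n"
        matrix = read_genotypes(io.StringIO(text))
        assert matrix.n_lines == 2 and matrix.n_markers == 3
        assert matrix.call("b", 1) == "AG"  # GA normalised
        assert matrix.call("b", 2) == ""

    def test_ragged_row_rejected_with_row_number(self):
        text = "line\tm1\tm2\na\tAA\n"
        with pytest.raises(GenotypeFormatError, match="row 2"):
            read_genotypes(io.StringIO(text))

    def test_bad_call_rejected(self):
        text = "line\tm1\na\tAGT\n"
        with pytest.raises(GenotypeFormatError, match="AGT"):
            read_genotypes(io.StringIO(text))

    def test_round_trip_with_map(self):
        matrix = toy_matrix()
        geno, mp = io.StringIO(), io.StringIO()
        write_genotypes(matrix, geno, mp)
        back = read_genotypes(io.StringIO(geno.getvalue()), io.StringIO(mp.getvalue()))
        assert back.lines == matrix.lines
        assert [m.name for m in back.markers] == [m.name for m in matrix.markers]
        assert back.row_calls("a") == matrix.row_calls("a")


class TestLocusSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AA", "AA", 1.0),
            ("AA", "GG", 0.0),
            ("AA", "AG", 0.5),
            ("AG", "GA", 1.0),
            ("AG", "AT", 0.5),
            ("CG", "AC", 0.5),  # shared allele in different sort positions
            ("AG", "", None),
            ("-", "AA", None),
        ],
    )
    def test_multiset_intersection_cases(self, a, b, expected):
        assert locus_similarity(a, b) == expected

    def test_half_score_for_every_het_hom_pair(self):
        for x, y in itertools.permutations("ACGT", 2):
            assert locus_similarity(x + x, x + y) == 0.5
            assert locus_similarity(x + y, y + x) == 1.0

    def test_symmetry_against_brute_force(self):
        calls = ["AA", "AG", "GG", "AT", "CC", ""]
        for a in calls:
            for b in calls:
                got = locus_similarity(a, b)
                assert got == locus_similarity(b, a)
                if a and b:
                    # brute-force multiset intersection
                    rem = list(b)
                    shared = 0
                    for ch in a:
                        if ch in rem:
                            rem.remove(ch)
                            shared += 1
                    assert got == shared / 2


class TestPairwiseSimilarity:
    def test_identical_and_complementary_rows(self):
        matrix = GenotypeMatrix(
            ["x", "y", "z"],
            ["m1", "m2"],
            [["AA", "GG"], ["AA", "GG"], ["CC", "TT"]],
        )
        assert pairwise_similarity(matrix, "x", "y") == (100.0, 2)
        assert pairwise_similarity(matrix, "x", "z") == (0.0, 2)

    def test_matches_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(10)
        calls = [
            [rng.choice(["AA", "AG", "GG", ""]) for _ in range(50)] for _ in range(6)
        ]
        matrix = GenotypeMatrix([f"l{i}" for i in range(6)], [f"m{j}" for j in range(50)], calls)
        for i in range(6):
            for j in range(6):
                scores = [
                    locus_similarity(calls[i][k], calls[j][k])
                    for k in range(50)
                    if calls[i][k] and calls[j][k]
                ]
                expected = (
                    (100.0 * sum(scores) / len(scores), len(scores)) if scores else None
                )
                got = pairwise_similarity(matrix, f"l{i}", f"l{j}")
                if expected is None:
                    assert got is None
                else:
                    assert got[1] == expected[1]
                    assert got[0] == pytest.approx(expected[0])

    def test_min_loci_filter(self):
        matrix = GenotypeMatrix(
            ["x", "y"], ["m1", "m2"], [["AA", "-"], ["AA", "-"]]
        )
        assert pairwise_similarity(matrix, "x", "y", min_loci=2) is None


class TestSimilarityMatrix:
    def test_diagonal_symmetry_and_oracle(self):
        rng = np.random.default_rng(20)
        calls = [
            [rng.choice(["AA", "AG", "GG", "TT", ""]) for _ in range(60)]
            for _ in range(8)
        ]
        matrix = GenotypeMatrix(
            [f"l{i}" for i in range(8)], [f"m{j}" for j in range(60)], calls
        )
        sim = similarity_matrix(matrix)
        assert np.allclose(sim.percent, sim.percent.T, equal_nan=True)
        for i in range(8):
            assert sim.percent[i, i] == 100.0
        for i in range(8):
            for j in range(8):
                expected = pairwise_similarity(matrix, f"l{i}", f"l{j}")
                if expected is None:
                    assert sim.n_loci[i, j] == 0
                else:
                    assert sim.percent[i, j] == pytest.approx(expected[0])

    def test_threshold_query_sorted_and_cutoffs(self):
        matrix = GenotypeMatrix(
            ["base", "twin", "far"],
            ["m1", "m2"],
            [["AA", "GG"], ["AA", "GG"], ["CC", "TT"]],
        )
        sim = similarity_matrix(matrix)
        assert threshold_similar(sim, "base", 100.0) == [("twin", 100.0)]
        assert [n for n, _ in threshold_similar(sim, "base", 0.0)] == ["twin", "far"]
        with pytest.raises(UnknownLineError):
            threshold_similar(sim, "nope", 50.0)


def oracle_trio(child: str, p1: str, p2: str) -> str:
    if not child or not p1 or not p2:
        return "untestable"
    return (
        "consistent"
        if all(allele in (p1 + p2) for allele in child)
        else "violation"
    )


class TestTrioConsistent:
    def test_both_parents_allele_a_child_allele_b_flagged(self):
        assert trio_consistent("GG", "AA", "AA") == "violation"

    def test_inbreeding_fixes_either_parental_allele(self):
        assert trio_consistent("AA", "AA", "GG") == "consistent"
        assert trio_consistent("GG", "AA", "GG") == "consistent"
        assert trio_consistent("AG", "AA", "GG") == "consistent"

    def test_exhaustive_biallelic_enumeration(self):
        calls = ["AA", "AG", "GG"]
        for child, p1, p2 in itertools.product(calls, repeat=3):
            assert trio_consistent(child, p1, p2) == oracle_trio(child, p1, p2)

    def test_all_missing_patterns_untestable(self):
        for pattern in itertools.product(["AA", ""], repeat=3):
            if "" in pattern:
                assert trio_consistent(*pattern) == "untestable"

    def test_multiallelic_calls(self):
        assert trio_consistent("CT", "CC", "TT") == "consistent"
        assert trio_consistent("CT", "CC", "GG") == "violation"


class TestCheckMendelian:
    def test_clean_simulation_has_zero_violations(self, small_truth):
        report = check_mendelian(small_truth.net, small_truth.matrix)
        assert report.n_violations == 0
        assert report.trios_tested == 30

    def test_single_bad_marker_flagged_once(self):
        net = build_net([ParentChildRecord("kid", "mum", "dad")])
        matrix = GenotypeMatrix(
            ["kid", "mum", "dad"],
            ["m1", "m2"],
            [["AA", "GG"], ["AA", "AA"], ["AA", "AA"]],
        )
        report = check_mendelian(net, matrix)
        assert report.n_violations == 1
        v = report.violations[0]
        assert (v.child, v.marker, v.child_call, v.rule) == ("kid", "m2", "GG", "trio")
        assert report.per_line_counts == {"kid": 1}

    def test_single_parent_rule_hom_vs_hom_only(self):
        net = build_net([ParentChildRecord("kid", "mum")])
        matrix = GenotypeMatrix(
            ["kid", "mum"],
            ["m1", "m2", "m3"],
            [["GG", "AG", "CC"], ["AA", "AA", "CC"]],
        )
        report = check_mendelian(net, matrix)
        # m1: hom vs different hom -> flagged; m2: het child untestable; m3 ok
        assert [v.marker for v in report.violations] == ["m1"]
        assert report.violations[0].rule == "single_parent"

    def test_disjoint_line_sets_rejected(self, quench_net):
        matrix = toy_matrix()
        with pytest.raises(PednetError):
            check_mendelian(quench_net, matrix)

    def test_report_tsv_output(self):
        net = build_net([ParentChildRecord("kid", "mum", "dad")])
        matrix = GenotypeMatrix(
            ["kid", "mum", "dad"], ["m1"], [["GG"], ["AA"], ["AA"]]
        )
        buf = io.StringIO()
        check_mendelian(net, matrix).write_tsv(buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].startswith("child\tmarker")
        assert lines[1].split("\t") == ["kid", "m1", "GG", "AA", "AA", "trio"]


class TestMatching:
    def test_self_query_ranks_first(self, small_truth):
        matrix = small_truth.matrix
        line = matrix.lines[5]
        ranked = match_genotype(matrix.row_calls(line), matrix, top_k=3)
        assert ranked[0][0] == line and ranked[0][1] == 100.0

    def test_all_missing_query_matches_nothing(self, small_truth):
        query = [""] * small_truth.matrix.n_markers
        assert match_genotype(query, small_truth.matrix) == []

    def test_length_mismatch_rejected(self, small_truth):
        with pytest.raises(PednetError):
            match_genotype(["AA"], small_truth.matrix)


class TestInferSecondParent:
    def test_true_parent_scores_one_and_ranks_first(self, small_truth):
        net, matrix = small_truth.net, small_truth.matrix
        child = "C020"
        p1, p2 = net.parents(child)
        ranked = infer_second_parent(net, matrix, child, p1, top_k=len(matrix.lines))
        by_name = dict((name, frac) for name, frac, _ in ranked)
        assert by_name[p2] == 1.0
        top_score = ranked[0][1]
        assert by_name[p2] == top_score  # rank 1 up to ties

    def test_child_and_descendants_excluded(self, small_truth):
        net, matrix = small_truth.net, small_truth.matrix
        child = "C005"
        p1, _ = net.parents(child)
        names = {name for name, _, _ in infer_second_parent(net, matrix, child, p1, top_k=999)}
        assert child not in names
        assert not (names & net.descendants(child))

    def test_ungenotyped_child_rejected(self, small_truth):
        with pytest.raises(PednetError):
            infer_second_parent(
                small_truth.net, small_truth.matrix, "missing-line", "F001"
            )

    def test_incompatible_founder_scores_below_one(self):
        net = build_net([ParentChildRecord("kid", "mum", "dad")])
        matrix = GenotypeMatrix(
            ["kid", "mum", "dad", "stranger"],
            ["m1", "m2"],
            [["GG", "TT"], ["AA", "TT"], ["GG", "TT"], ["CC", "CC"]],
        )
        ranked = infer_second_parent(net, matrix, "kid", "mum", top_k=10)
        scores = dict((name, frac) for name, frac, _ in ranked)
        assert scores["dad"] == 1.0
        assert scores["stranger"] < 1.0
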