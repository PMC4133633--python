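import random

import pytest

from pednet import ParentChildRecord, build_net, simulate_breeding_program, SimConfig
from pednet.notation import CrossTree, cross, founder


@pytest.fixture
def quench_net():
    """The worked single-cross pedigree: Quench = Sebastian x Drum."""
    return build_net([ParentChildRecord("Quench", "Sebastian", "Drum")])


@pytest.fixture
def diamond_net():
    """A -> C <- B, C -> D: one cross plus a single-parent derivation."""
    return build_net(
        [
            ParentChildRecord("C", "A", "B"),
            ParentChildRecord("D", "C", "E"),
        ]
    )


@pytest.fixture
def small_truth():
    return simulate_breeding_program(
        SimConfig(n_founders=10, n_crosses=30, n_markers=120, seed=5)
    )


def random_cross_tree(rng: random.Random, n_founders: int = 6, max_depth: int = 5) -> CrossTree:
    """Random binary cross tree over a small founder alphabet."""
    names = [f"L{i}" for i in range(1, n_founders + 1)]

    def build(depth: int) -> CrossTree:
        if depth >= max_depth or rng.random() < 0.35:
            return founder(rng.choice(names))
        return cross(build(depth + 1), build(depth + 1))

    node = build(0)
    if node.is_founder:  # ensure at least one cross
        node = cross(node, founder(rng.choice(names)))
    return node


def random_net_records(rng: random.Random, n_founders: int, n_crosses: int):
    """Random acyclic parent/child records (parents always earlier lines)."""
    names = [f"F{i}" for i in range(n_founders)]
    records = [ParentChildRecord(n) for n in names]
    for c in range(n_crosses):
        child = f"X{c}"
        p1 = rng.choice(names)
        p2 = p1 if rng.random() < 0.1 else rng.choice(names)
        records.append(ParentChildRecord(child, p1, p2))
        names.append(child)
    return records
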