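"""Layered (Sugiyama-style) layout of a pedigree net, rendered to SVG.

The pipeline is the classic one: layer assignment (generations, by longest
path), subdivision of multi-generation edges with dummy vertices, crossing
reduction by iterated barycenter sweeps, then coordinate assignment on a
fixed grid.  Layer 0 (the oldest founders) is drawn at the top and
generations run downward; edges are straight polylines routed through their
dummy vertices.  Force-directed layouts are deliberately not offered — they
destroy the top-down generation topology a pedigree reading depends on.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import PednetError, UnknownLineError
from .net import PedigreeNet, assign_generations
from .overlay import NodeStyle

__all__ = [
    "LayoutOptions",
    "LayoutResult",
    "layered_layout",
    "layout_local",
    "count_crossings",
    "render_svg",
]

EdgeKey = tuple[str, str, str]  # (parent, child, role)


@dataclass(frozen=True)
class LayoutOptions:
    """Tunables for the layered layout.

    ``sweeps`` caps the barycenter down/up passes; ``layer_gap`` and
    ``node_gap`` are abstract drawing units; ``seed`` shuffles the initial
    per-layer order (0 keeps plain topological discovery order).
    """

    sweeps: int = 8
    layer_gap: float = 60.0
    node_gap: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.layer_gap <= 0 or self.node_gap <= 0:
            raise ValueError("gaps must be positive")


@dataclass
class LayoutResult:
    """Positions of real nodes, per-edge dummy routes and per-layer orders.

    ``positions`` maps a line to ``(x, layer)``; ``dummy_chains`` maps an
    edge to the ordered ``(x, layer)`` points of its intermediate dummy
    vertices (empty for edges spanning one layer); ``layer_orders`` holds
    the final left-to-right order of real and dummy ids per layer.
    """

    positions: dict[str, tuple[float, int]] = field(default_factory=dict)
    dummy_chains: dict[EdgeKey, list[tuple[float, int]]] = field(default_factory=dict)
    layer_orders: dict[int, list] = field(default_factory=dict)
    node_gap: float = 30.0
    layer_gap: float = 60.0

    def edge_route(self, parent: str, child: str, role: str) -> list[tuple[float, int]]:
        """Full polyline for one edge: parent, dummy points, child."""
        key = (parent, child, role)
        return (
            [self.positions[parent]]
            + self.dummy_chains.get(key, [])
            + [self.positions[child]]
        )


def _initial_orders(
    net: PedigreeNet,
    layers: dict[str, int],
    seed: int,
) -> tuple[dict[int, list], dict[EdgeKey, list], dict]:
    """Build per-layer orders including dummy vertices for long edges.

    Returns (orders, chains, segments) where ``chains`` maps each edge to
    its dummy-id list and ``segments`` maps each adjacent layer pair to its
    (upper_id, lower_id) segment list.
    """
    n_layers = (max(layers.values()) + 1) if layers else 0
    orders: dict[int, list] = {k: [] for k in range(n_layers)}
    # discovery order = layer assignment order (topological)
    for name in layers:
        orders[layers[name]].append(name)
    chains: dict[EdgeKey, list] = {}
    segments: dict[int, list[tuple]] = {k: [] for k in range(n_layers - 1)}
    for parent, child, role in net.edges():
        key = (parent, child, role)
        lp, lc = layers[parent], layers[child]
        dummies = []
        prev = parent
        for mid in range(lp + 1, lc):
            dummy = ("dummy", key, mid)
            orders[mid].append(dummy)
            segments[mid - 1].append((prev, dummy))
            dummies.append(dummy)
            prev = dummy
        segments[lc - 1].append((prev, child))
        chains[key] = dummies
    if seed:
        rng = random.Random(seed)
        for order in orders.values():
            rng.shuffle(order)
    return orders, chains, segments


def _crossings_of_orders(
    orders: dict[int, list], segments: dict[int, list[tuple]]
) -> int:
    """Count pairwise segment crossings between every adjacent layer pair."""
    total = 0
    for k, segs in segments.items():
        up = {node: i for i, node in enumerate(orders[k])}
        down = {node: i for i, node in enumerate(orders[k + 1])}
        pairs = sorted((up[u], down[v]) for u, v in segs)
        total += _count_inversions([v for _, v in pairs])
    return total


def _count_inversions(seq: list[int]) -> int:
    """Merge-sort inversion count (pairs i<j with seq[i] > seq[j])."""
    if len(seq) < 2:
        return 0
    mid = len(seq) // 2
    left, right = seq[:mid], seq[mid:]
    inv = _count_inversions(left) + _count_inversions(right)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            inv += len(left) - i
            merged.append(right[j])
            j += 1
    seq[:] = merged + left[i:] + right[j:]
    return inv


def _barycenter_pass(
    orders: dict[int, list],
    segments: dict[int, list[tuple]],
    downward: bool,
) -> None:
    """One in-place barycenter sweep; ties keep the previous order."""
    layer_ids = sorted(orders)
    scan = layer_ids[1:] if downward else layer_ids[-2::-1]
    for k in scan:
        ref = k - 1 if downward else k + 1
        seg_list = segments[min(k, ref)]
        ref_pos = {node: i for i, node in enumerate(orders[ref])}
        neigh: dict = {node: [] for node in orders[k]}
        for u, v in seg_list:
            here, there = (v, u) if downward else (u, v)
            neigh[here].append(ref_pos[there])
        current = {node: i for i, node in enumerate(orders[k])}
        orders[k].sort(
            key=lambda node: (
                sum(neigh[node]) / len(neigh[node]) if neigh[node] else current[node],
                current[node],
            )
        )


def layered_layout(net: PedigreeNet, options: LayoutOptions | None = None) -> LayoutResult:
    """Compute the layered layout of a pedigree net.

    Layers come from generation assignment; long edges are subdivided with
    one dummy vertex per intermediate layer; barycenter sweeps (down, then
    up) run until crossings stop improving or the sweep cap is reached, and
    the best order seen is kept — so the result never has more crossings
    than the initial order.  Fully deterministic for a fixed seed.
    """
    options = options or LayoutOptions()
    layers = assign_generations(net)
    result = LayoutResult(node_gap=options.node_gap, layer_gap=options.layer_gap)
    if not layers:
        return result
    orders, chains, segments = _initial_orders(net, layers, options.seed)
    best = {k: list(v) for k, v in orders.items()}
    best_crossings = _crossings_of_orders(orders, segments)
    for _ in range(options.sweeps):
        _barycenter_pass(orders, segments, downward=True)
        _barycenter_pass(orders, segments, downward=False)
        crossings = _crossings_of_orders(orders, segments)
        if crossings < best_crossings:
            best_crossings = crossings
            best = {k: list(v) for k, v in orders.items()}
        else:
            break
    result.layer_orders = best
    pos: dict = {}
    for layer, order in best.items():
        for i, node in enumerate(order):
            pos[node] = (i * options.node_gap, layer)
    result.positions = {n: p for n, p in pos.items() if isinstance(n, str)}
    result.dummy_chains = {
        key: [pos[d] for d in dummies] for key, dummies in chains.items()
    }
    return result


def layout_local(
    subnet: PedigreeNet,
    options: LayoutOptions | None = None,
    focus: str | None = None,
) -> LayoutResult:
    """Lay out a local view (from :meth:`PedigreeNet.local_view`).

    Generations are recomputed on the sub-net, so the shallowest present
    layer is re-based to 0.  When ``focus`` names the selected line, the
    whole drawing is translated so that line sits at x = 0, centring it.
    """
    result = layered_layout(subnet, options)
    if focus is not None:
        if focus not in result.positions:
            raise UnknownLineError(f"unknown line {focus!r}")
        dx = result.positions[focus][0]
        if dx:
            result.positions = {
                n: (x - dx, layer) for n, (x, layer) in result.positions.items()
            }
            result.dummy_chains = {
                k: [(x - dx, layer) for x, layer in chain]
                for k, chain in result.dummy_chains.items()
            }
    return result


def count_crossings(result: LayoutResult) -> int:
    """Number of crossing segment pairs between adjacent layers.

    Two segments between the same pair of adjacent layers cross when their
    endpoint orders invert; segments sharing an endpoint do not cross.
    """
    index = {
        layer: {node: i for i, node in enumerate(order)}
        for layer, order in result.layer_orders.items()
    }
    total = 0
    seg_by_gap: dict[int, list[tuple[int, int]]] = {}
    for key in result.dummy_chains:
        parent, child, _role = key
        route_nodes = (
            [parent]
            + [("dummy", key, point[1]) for point in result.dummy_chains[key]]
            + [child]
        )
        layer = result.positions[parent][1]
        for a, b in zip(route_nodes, route_nodes[1:]):
            seg_by_gap.setdefault(layer, []).append(
                (index[layer][a], index[layer + 1][b])
            )
            layer += 1
    for gap, segs in seg_by_gap.items():
        pairs = sorted(segs)
        total += _count_inversions([v for _, v in pairs])
    return total


# ---------------------------------------------------------------------------
# SVG rendering

_MARGIN = 40.0
_FONT = 10


def render_svg(
    result: LayoutResult,
    styles: dict[str, NodeStyle],
    stream,
) -> None:
    """Render a layout as SVG 1.1: one circle per line, one polyline per
    edge, labels beneath nodes; layer 0 at the top.  Output is
    deterministic for identical input."""
    missing = sorted(set(result.positions) - set(styles))
    if missing:
        raise PednetError(f"no style for node {missing[0]!r}")
    xs = [x for x, _ in result.positions.values()] or [0.0]
    for chain in result.dummy_chains.values():
        xs.extend(x for x, _ in chain)
    min_x, max_x = min(xs), max(xs)
    n_layers = max((layer for _, layer in result.positions.values()), default=0) + 1

    def sx(x: float) -> float:
        return _MARGIN + (x - min_x)

    def sy(layer: int) -> float:
        return _MARGIN + layer * result.layer_gap

    width = (max_x - min_x) + 2 * _MARGIN
    height = (n_layers - 1) * result.layer_gap + 2 * _MARGIN
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.1f}" height="{height:.1f}" '
        f'viewBox="0 0 {width:.1f} {height:.1f}">',
    ]
    for parent, child, role in sorted(result.dummy_chains):
        route = result.edge_route(parent, child, role)
        points = " ".join(f"{sx(x):.1f},{sy(layer):.1f}" for x, layer in route)
        out.append(
            f'  <polyline points="{points}" fill="none" '
            f'stroke="#888888" stroke-width="1"/>'
        )
    for name in sorted(result.positions):
        x, layer = result.positions[name]
        style = styles[name]
        out.append(
            f'  <circle cx="{sx(x):.1f}" cy="{sy(layer):.1f}" '
            f'r="{style.size:.1f}" fill="{style.color}" '
            f'stroke="#333333" stroke-width="0.5"/>'
        )
        out.append(
            f'  <text x="{sx(x):.1f}" y="{sy(layer) + style.size + _FONT:.1f}" '
            f'font-size="{_FONT}" text-anchor="middle" '
            f'font-family="sans-serif">{_escape(name)}</text>'
        )
    out.append("</svg>")
    stream.write("\n".join(out) + "\n")


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
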