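"""The pedigree net: a DAG of plant lines with up to two parent roles per line.

Plant pedigrees are not trees.  Inbred lines persist as seed for decades, so
founders from the top of the graph are crossed directly into modern
generations, selfing puts one line in both parental roles of a cross, and
heavily used parents feed dozens of children.  The resulting structure — a
directed acyclic multigraph whose edges can span many generations — is what
this module models and queries.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

from .errors import PedigreeStructureError, UnknownLineError
from .notation import ParentChildRecord

__all__ = [
    "PedigreeNet",
    "build_net",
    "assign_generations",
    "classify_lines",
]

ROLES = ("parent_1", "parent_2")


@dataclass
class PedigreeNet:
    """Directed acyclic multigraph of plant lines.

    Each line has at most two parent roles (``parent_1``, ``parent_2``); the
    same parent may fill both (selfing).  ``attributes`` carries optional
    passport data (e.g. ecotype) per line.
    """

    _parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    _children: dict[str, set[str]] = field(default_factory=dict)
    _cross_type: dict[str, str | None] = field(default_factory=dict)
    attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    def _ensure(self, name: str) -> None:
        self._parents.setdefault(name, (None, None))
        self._children.setdefault(name, set())

    def add_record(self, record: ParentChildRecord) -> None:
        self._ensure(record.child)
        existing = self._parents[record.child]
        new = (record.parent_1, record.parent_2)
        if existing != (None, None) and existing != new:
            raise PedigreeStructureError(
                f"line {record.child!r} defined twice with different parents: "
                f"{existing} vs {new} — re-used names create false "
                f"relationship joins and must be disambiguated upstream"
            )
        self._parents[record.child] = new
        self._cross_type[record.child] = record.cross_type
        for parent in new:
            if parent is not None:
                self._ensure(parent)
                self._children[parent].add(record.child)

    # -- basic queries ------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def lines(self) -> list[str]:
        return sorted(self._parents)

    def _check(self, name: str) -> None:
        if name not in self._parents:
            raise UnknownLineError(f"unknown line {name!r}")

    def parents(self, line: str) -> tuple[str, ...]:
        """The (parent_1, parent_2) pair, with missing roles dropped."""
        self._check(line)
        return tuple(p for p in self._parents[line] if p is not None)

    def parent_roles(self, line: str) -> tuple[str | None, str | None]:
        self._check(line)
        return self._parents[line]

    def cross_type(self, line: str) -> str | None:
        self._check(line)
        return self._cross_type.get(line)

    def is_founder(self, line: str) -> bool:
        """A founder has no recorded parents."""
        return not self.parents(line)

    def progeny(self, line: str) -> set[str]:
        """All children in which ``line`` fills at least one parent role."""
        self._check(line)
        return set(self._children[line])

    def usage_count(self, line: str) -> int:
        """Number of distinct crosses this line parented (selfing counts once)."""
        return len(self.progeny(line))

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """All (parent, child, role) edges; a selfing yields two edges."""
        for child in sorted(self._parents):
            p1, p2 = self._parents[child]
            if p1 is not None:
                yield (p1, child, "parent_1")
            if p2 is not None:
                yield (p2, child, "parent_2")

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    # -- traversal ----------------------------------------------------------

    def ancestors(self, line: str, k: int | None = None) -> set[str]:
        """Lines reachable through parent edges within ``k`` generations
        (``None`` = unlimited).  Excludes ``line`` itself."""
        self._check(line)
        return self._bfs(line, k, lambda n: self.parents(n))

    def descendants(self, line: str, k: int | None = None) -> set[str]:
        """Mirror of :meth:`ancestors` over child edges."""
        self._check(line)
        return self._bfs(line, k, lambda n: self._children[n])

    def _bfs(self, start: str, k: int | None, step) -> set[str]:
        if k is not None and k < 0:
            raise ValueError("generation count must be >= 0")
        seen: set[str] = set()
        frontier = {start}
        depth = 0
        while frontier and (k is None or depth < k):
            frontier = {n for f in frontier for n in step(f)} - seen - {start}
            seen |= frontier
            depth += 1
        return seen

    def local_view(self, line: str, back: int, forward: int) -> "PedigreeNet":
        """Induced sub-net around ``line``: its ancestors to depth ``back``
        and descendants to depth ``forward``.  Parent roles whose line falls
        outside the window are dropped."""
        keep = {line} | self.ancestors(line, back) | self.descendants(line, forward)
        sub = PedigreeNet()
        for name in sorted(keep):
            sub._ensure(name)
            p1, p2 = self._parents[name]
            p1 = p1 if p1 in keep else None
            p2 = p2 if p2 in keep else None
            if p2 is not None and p1 is None:
                # keep the surviving role in slot 1 to preserve the invariant
                p1, p2 = p2, None
            sub._parents[name] = (p1, p2)
            sub._cross_type[name] = self._cross_type.get(name)
            for parent in (p1, p2):
                if parent is not None:
                    sub._ensure(parent)
                    sub._children[parent].add(name)
            if name in self.attributes:
                sub.attributes[name] = dict(self.attributes[name])
        return sub

    def selection_edges(self, line: str) -> set[tuple[str, str, str]]:
        """Edges lying on ancestor or descendant paths of ``line`` — the
        batch equivalent of de-cluttering the display after selecting a node."""
        self._check(line)
        anc = self.ancestors(line)
        desc = self.descendants(line)
        kept: set[tuple[str, str, str]] = set()
        for parent, child, role in self.edges():
            if parent in anc and (child in anc or child == line):
                kept.add((parent, child, role))
            elif (parent in desc or parent == line) and child in desc:
                kept.add((parent, child, role))
        return kept

    def degree_summary(self, line: str) -> tuple[int, int, list[str]]:
        """(ingoing parent roles, outgoing parent-role edges, sorted progeny).

        The hover summary of the interactive tool, as a query: how many
        edges enter the node, how many leave, and which children they reach.
        """
        self._check(line)
        in_count = len(self.parents(line))
        out_count = sum(
            1
            for child in self._children[line]
            for p in self._parents[child]
            if p == line
        )
        return in_count, out_count, sorted(self._children[line])

    def search_lines(self, pattern: str) -> list[str]:
        """Case-insensitive wildcard search: ``*`` any run, ``?`` one char."""
        if not pattern:
            raise ValueError("search pattern must be non-empty")
        rx = re.compile(fnmatch.translate(pattern), re.IGNORECASE)
        return sorted(name for name in self._parents if rx.match(name))

    def export_selection(self, names: Iterable[str], stream: IO[str]) -> int:
        """Write an export list (one name per line, order and duplicates
        preserved) and return the number of rows written."""
        names = list(names)
        missing = [n for n in names if n not in self._parents]
        if missing:
            raise UnknownLineError(f"unknown lines: {', '.join(sorted(set(missing)))}")
        for name in names:
            stream.write(name + "\n")
        return len(names)

    # -- interop ------------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._parents)
        for parent, child, role in self.edges():
            g.add_edge(parent, child, role=role)
        return g


def build_net(records: Iterable[ParentChildRecord]) -> PedigreeNet:
    """Reconstruct a pedigree net from atomised parent/child records.

    Parents referenced but never defined become founder lines.  Validation
    rejects cycles (a line can never be its own ancestor) and duplicate child
    definitions with conflicting parents.
    """
    net = PedigreeNet()
    for record in records:
        net.add_record(record)
    graph = nx.DiGraph()
    graph.add_nodes_from(net._parents)
    graph.add_edges_from((p, c) for p, c, _ in net.edges())
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return net
    path = " -> ".join([edge[0] for edge in cycle] + [cycle[-1][1]])
    raise PedigreeStructureError(f"pedigree contains a cycle: {path}")


def assign_generations(net: PedigreeNet) -> dict[str, int]:
    """Longest-path layering: founders at 0, every child one below its
    deepest parent.  Children therefore always sit strictly below all of
    their parents, preserving the top-down generation topology."""
    graph = nx.DiGraph()
    graph.add_nodes_from(net._parents)
    graph.add_edges_from((p, c) for p, c, _ in net.edges())
    layers: dict[str, int] = {}
    for name in nx.topological_sort(graph):
        parent_layers = [layers[p] for p in net.parents(name)]
        layers[name] = 1 + max(parent_layers) if parent_layers else 0
    return layers


def classify_lines(net: PedigreeNet, principal_threshold: int = 5) -> dict[str, str]:
    """Partition lines into usage classes.

    * ``terminal`` — released but never used as a parent (usage 0);
    * ``principal`` — the workhorses, used in at least ``principal_threshold``
      crosses;
    * ``flanking`` — founders brought in for diversity, used at least once
      but below the principal threshold;
    * ``intermediate`` — everything else.
    """
    if principal_threshold < 1:
        raise ValueError("principal_threshold must be >= 1")
    roles: dict[str, str] = {}
    for line in net.lines:
        usage = net.usage_count(line)
        if usage == 0:
            roles[line] = "terminal"
        elif usage >= principal_threshold:
            roles[line] = "principal"
        elif net.is_founder(line):
            roles[line] = "flanking"
        else:
            roles[line] = "intermediate"
    return roles
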