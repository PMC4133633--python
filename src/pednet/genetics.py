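"""Genotype matrices, allele-sharing similarity and pedigree QC.

The data model is the flat SNP matrix used for inbred crop panels: lines by
markers, each cell an unordered diploid call such as ``AA`` or ``AG``
(normalised so ``GA`` == ``AG``), with ``-`` or blank for missing.  On top
of it sit:

* **identity-by-state similarity** — the fraction of shared alleles per
  locus (1, 0.5 or 0), averaged over the loci where both lines are called,
  reported as a percentage;
* **Mendelian consistency checking** — every allele of a child must come
  from one of its parents.  Because the named "child" of a plant cross is
  an inbred descendant of that cross, the test is the *union* rule (child
  alleles a subset of the combined parental alleles), not strict
  one-allele-per-parent transmission: ``AA`` offspring of an ``AA`` x ``GG``
  cross is legitimate;
* **genotype matching** and **second-parent inference** for resolving
  mislabelled or incompletely recorded lines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .errors import GenotypeFormatError, PednetError, UnknownLineError
from .net import PedigreeNet

__all__ = [
    "Marker",
    "GenotypeMatrix",
    "SimilarityMatrix",
    "ConsistencyReport",
    "read_genotypes",
    "write_genotypes",
    "normalise_call",
    "locus_similarity",
    "pairwise_similarity",
    "similarity_matrix",
    "threshold_similar",
    "trio_consistent",
    "check_mendelian",
    "match_genotype",
    "infer_second_parent",
]

MISSING = ""


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str | None = None
    position: float | None = None


def normalise_call(cell: str) -> str:
    """Normalise a raw cell to a sorted two-letter call or '' for missing."""
    cell = cell.strip()
    if cell in ("", "-", "--", "NN", "N"):
        return MISSING
    if len(cell) != 2 or not cell.isalpha():
        raise GenotypeFormatError(
            f"invalid genotype call {cell!r}: expected two letters or '-'"
        )
    a, b = sorted(cell.upper())
    return a + b


class GenotypeMatrix:
    """Lines x markers matrix of normalised diploid calls.

    Internally stored as two (n_lines, n_markers) arrays of single allele
    characters (sorted within a call, '' for missing) so per-locus
    operations vectorise across markers.
    """

    def __init__(self, lines: Sequence[str], markers: Sequence[Marker | str], calls):
        self.lines = list(lines)
        self.markers = [
            m if isinstance(m, Marker) else Marker(m) for m in markers
        ]
        if len(set(self.lines)) != len(self.lines):
            raise GenotypeFormatError("duplicate line names in genotype matrix")
        if len({m.name for m in self.markers}) != len(self.markers):
            raise GenotypeFormatError("duplicate marker names in genotype matrix")
        n, m = len(self.lines), len(self.markers)
        self.a1 = np.full((n, m), "", dtype="<U1")
        self.a2 = np.full((n, m), "", dtype="<U1")
        for i in range(n):
            row = calls[i]
            if len(row) != m:
                raise GenotypeFormatError(
                    f"row {i + 1} has {len(row)} calls, expected {m}"
                )
            for j, cell in enumerate(row):
                call = normalise_call(cell) if cell else MISSING
                if call:
                    self.a1[i, j] = call[0]
                    self.a2[i, j] = call[1]
        self._index = {name: i for i, name in enumerate(self.lines)}

    @classmethod
    def from_allele_arrays(
        cls,
        lines: Sequence[str],
        markers: Sequence[Marker | str],
        a1: np.ndarray,
        a2: np.ndarray,
    ) -> "GenotypeMatrix":
        """Build directly from pre-normalised allele arrays (a1 <= a2
        elementwise, '' for missing in both) without per-cell parsing."""
        obj = cls.__new__(cls)
        obj.lines = list(lines)
        obj.markers = [m if isinstance(m, Marker) else Marker(m) for m in markers]
        obj.a1 = np.asarray(a1, dtype="<U1").copy()
        obj.a2 = np.asarray(a2, dtype="<U1").copy()
        if obj.a1.shape != (len(obj.lines), len(obj.markers)):
            raise GenotypeFormatError("allele array shape does not match names")
        obj._index = {name: i for i, name in enumerate(obj.lines)}
        return obj

    # -- access -------------------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __contains__(self, line: str) -> bool:
        return line in self._index

    def row_index(self, line: str) -> int:
        try:
            return self._index[line]
        except KeyError:
            raise UnknownLineError(f"line {line!r} not in genotype matrix")

    def call(self, line: str, marker_idx: int) -> str:
        i = self.row_index(line)
        a = self.a1[i, marker_idx]
        return a + self.a2[i, marker_idx] if a else MISSING

    def row_calls(self, line: str) -> list[str]:
        i = self.row_index(line)
        return [
            (a + b) if a else MISSING
            for a, b in zip(self.a1[i], self.a2[i])
        ]

    def present(self, line: str) -> np.ndarray:
        """Boolean mask of non-missing calls for one line."""
        return self.a1[self.row_index(line)] != ""

    def heterozygosity(self, line: str) -> float:
        """Fraction of called loci that are heterozygous (QC statistic;
        inbred lines should stay below ~0.5%)."""
        i = self.row_index(line)
        called = self.a1[i] != ""
        if not called.any():
            return float("nan")
        return float((self.a1[i][called] != self.a2[i][called]).mean())


# ---------------------------------------------------------------------------
# File format: tab-delimited, header = marker names, first column = line name


def read_genotypes(stream: IO[str], map_stream: IO[str] | None = None) -> GenotypeMatrix:
    """Read a flat tab-delimited genotype file (lines x markers).

    Header row holds marker names; each data row is a line name followed by
    two-letter calls ('-'/blank for missing).  An optional map file
    (``marker<TAB>chromosome<TAB>position``) is joined by marker name.
    """
    rows = [line.rstrip("\n").split("\t") for line in stream]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise GenotypeFormatError("empty genotype file")
    header = rows[0]
    marker_names = [cell.strip() for cell in header[1:]]
    markers: list[Marker | str] = list(marker_names)
    if map_stream is not None:
        positions = {}
        for raw in map_stream:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0].strip():
                positions[parts[0].strip()] = (
                    parts[1].strip(),
                    float(parts[2]) if parts[2].strip() else None,
                )
        markers = [
            Marker(name, *positions[name]) if name in positions else Marker(name)
            for name in marker_names
        ]
    lines = []
    calls = []
    for rownum, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise GenotypeFormatError(
                f"row {rownum}: {len(row)} columns, expected {len(header)}"
            )
        lines.append(row[0].strip())
        try:
            calls.append([normalise_call(cell) for cell in row[1:]])
        except GenotypeFormatError as exc:
            raise GenotypeFormatError(f"row {rownum}: {exc}") from exc
    return GenotypeMatrix(lines, markers, calls)


def write_genotypes(matrix: GenotypeMatrix, stream: IO[str], map_stream: IO[str] | None = None) -> None:
    stream.write("line\t" + "\t".join(m.name for m in matrix.markers) + "\n")
    for line in matrix.lines:
        cells = [call if call else "-" for call in matrix.row_calls(line)]
        stream.write(line + "\t" + "\t".join(cells) + "\n")
    if map_stream is not None:
        for m in matrix.markers:
            pos = "" if m.position is None else f"{m.position:g}"
            map_stream.write(f"{m.name}\t{m.chromosome or ''}\t{pos}\n")


# ---------------------------------------------------------------------------
# Allele-sharing similarity


def locus_similarity(call_a: str, call_b: str) -> float | None:
    """Shared-allele fraction at one locus: multiset intersection / 2.

    ``None`` when either call is missing.  Examples: (AA, AA) -> 1.0,
    (AA, AG) -> 0.5, (AA, GG) -> 0.0, (AG, GA) -> 1.0.
    """
    a = normalise_call(call_a) if call_a else MISSING
    b = normalise_call(call_b) if call_b else MISSING
    if not a or not b:
        return None
    if a[0] == a[1]:
        shared = (b[0] == a[0]) + (b[1] == a[0])
    else:
        shared = min(1, (b[0] == a[0]) + (b[1] == a[0])) + min(
            1, (b[0] == a[1]) + (b[1] == a[1])
        )
    return shared / 2.0


def _shared_alleles(a1, a2, b1, b2) -> np.ndarray:
    """Vectorised multiset-intersection count between sorted call arrays."""
    hom = a1 == a2
    cnt1 = (b1 == a1).astype(np.int8) + (b2 == a1)
    cnt2 = (b1 == a2).astype(np.int8) + (b2 == a2)
    return np.where(hom, cnt1, np.minimum(cnt1, 1) + np.minimum(cnt2, 1))


def _row_similarity(
    matrix: GenotypeMatrix, qa1, qa2, i: int
) -> tuple[float, int] | None:
    both = (qa1 != "") & (matrix.a1[i] != "")
    n = int(both.sum())
    if n == 0:
        return None
    shared = _shared_alleles(
        qa1[both], qa2[both], matrix.a1[i][both], matrix.a2[i][both]
    )
    return float(100.0 * shared.sum() / (2.0 * n)), n


def pairwise_similarity(
    matrix: GenotypeMatrix, line_a: str, line_b: str, min_loci: int = 1
) -> tuple[float, int] | None:
    """Percent allele-sharing similarity over co-called loci.

    Returns ``(percent, n_loci)`` or ``None`` when fewer than ``min_loci``
    loci are co-called.
    """
    i = matrix.row_index(line_a)
    out = _row_similarity(matrix, matrix.a1[i], matrix.a2[i], matrix.row_index(line_b))
    if out is None or out[1] < min_loci:
        return None
    return out


@dataclass
class SimilarityMatrix:
    """All-by-all percent similarity with per-pair co-called locus counts.

    ``percent`` is symmetric with NaN where no loci are shared; the
    diagonal is 100 wherever a line has at least one call.
    """

    lines: list[str]
    percent: np.ndarray
    n_loci: np.ndarray
    _index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.lines)}

    def get(self, a: str, b: str) -> tuple[float, int] | None:
        try:
            i, j = self._index[a], self._index[b]
        except KeyError as exc:
            raise UnknownLineError(f"unknown line {exc.args[0]!r}")
        if self.n_loci[i, j] == 0:
            return None
        return float(self.percent[i, j]), int(self.n_loci[i, j])


def similarity_matrix(matrix: GenotypeMatrix, min_loci: int = 1) -> SimilarityMatrix:
    """Compute the full symmetric all-by-all similarity matrix."""
    n = matrix.n_lines
    percent = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i, n):
            out = _row_similarity(matrix, matrix.a1[i], matrix.a2[i], j)
            if out is not None and out[1] >= min_loci:
                percent[i, j] = percent[j, i] = out[0]
                counts[i, j] = counts[j, i] = out[1]
    return SimilarityMatrix(list(matrix.lines), percent, counts)


def threshold_similar(
    sim: SimilarityMatrix, base: str, cutoff: float
) -> list[tuple[str, float]]:
    """Lines at least ``cutoff`` percent similar to ``base``, most similar
    first (ties broken by name) — the batch form of the similarity slider."""
    if not 0 <= cutoff <= 100:
        raise ValueError("cutoff must be between 0 and 100")
    if base not in sim._index:
        raise UnknownLineError(f"unknown line {base!r}")
    i = sim._index[base]
    hits = [
        (name, float(sim.percent[i, j]))
        for j, name in enumerate(sim.lines)
        if j != i and sim.n_loci[i, j] > 0 and sim.percent[i, j] >= cutoff
    ]
    return sorted(hits, key=lambda item: (-item[1], item[0]))


# ---------------------------------------------------------------------------
# Mendelian consistency


def trio_consistent(child: str, p1: str, p2: str) -> str:
    """Union-rule check of one trio at one locus.

    ``untestable`` when any call is missing; ``violation`` when some child
    allele occurs in neither parent; ``consistent`` otherwise.
    """
    c = normalise_call(child) if child else MISSING
    a = normalise_call(p1) if p1 else MISSING
    b = normalise_call(p2) if p2 else MISSING
    if not c or not a or not b:
        return "untestable"
    union = set(a) | set(b)
    return "consistent" if set(c) <= union else "violation"


@dataclass
class Violation:
    child: str
    marker: str
    child_call: str
    parent_calls: tuple[str, ...]
    rule: str  # "trio" or "single_parent"


@dataclass
class ConsistencyReport:
    """Outcome of a net-wide Mendelian check.

    ``violations`` lists every flagged (child, marker) pair;
    ``per_line_counts`` aggregates them per child; ``loci_tested`` counts
    testable (child, marker) combinations; ``heterozygosity`` is the
    per-line heterozygous fraction reported for QC alongside.
    """

    violations: list[Violation]
    per_line_counts: dict[str, int]
    loci_tested: int
    trios_tested: int
    heterozygosity: dict[str, float]

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("child\tmarker\tchild_call\tp1_call\tp2_call\trule\n")
        for v in self.violations:
            p1 = v.parent_calls[0] if v.parent_calls else ""
            p2 = v.parent_calls[1] if len(v.parent_calls) > 1 else ""
            stream.write(
                f"{v.child}\t{v.marker}\t{v.child_call}\t{p1}\t{p2}\t{v.rule}\n"
            )


def check_mendelian(net: PedigreeNet, matrix: GenotypeMatrix) -> ConsistencyReport:
    """Check every genotyped child in the net against its genotyped parents.

    Children with both parents genotyped get the trio union rule at every
    marker.  Children with exactly one genotyped parent get a conservative
    single-parent rule: flagged only when parent and child are homozygous
    for different alleles (anything weaker is untestable without the second
    parent).
    """
    shared = [line for line in net.lines if line in matrix]
    if not shared:
        raise PednetError("pedigree and genotype matrix share no lines")
    marker_names = [m.name for m in matrix.markers]
    violations: list[Violation] = []
    per_line: dict[str, int] = {}
    loci_tested = 0
    trios = 0
    for child in shared:
        parents = net.parents(child)
        genotyped = [p for p in parents if p in matrix]
        if not parents or not genotyped:
            continue
        ci = matrix.row_index(child)
        c1, c2 = matrix.a1[ci], matrix.a2[ci]
        child_called = c1 != ""
        if len(parents) == 2 and len(genotyped) == 2:
            trios += 1
            p1i = matrix.row_index(parents[0])
            p2i = matrix.row_index(parents[1])
            u1, u2 = matrix.a1[p1i], matrix.a2[p1i]
            v1, v2 = matrix.a1[p2i], matrix.a2[p2i]
            testable = child_called & (u1 != "") & (v1 != "")
            in_union_1 = (c1 == u1) | (c1 == u2) | (c1 == v1) | (c1 == v2)
            in_union_2 = (c2 == u1) | (c2 == u2) | (c2 == v1) | (c2 == v2)
            bad = testable & ~(in_union_1 & in_union_2)
            loci_tested += int(testable.sum())
            for j in np.flatnonzero(bad):
                violations.append(
                    Violation(
                        child,
                        marker_names[j],
                        c1[j] + c2[j],
                        (u1[j] + u2[j], v1[j] + v2[j]),
                        "trio",
                    )
                )
        else:
            pi = matrix.row_index(genotyped[0])
            u1, u2 = matrix.a1[pi], matrix.a2[pi]
            testable = child_called & (u1 != "") & (u1 == u2) & (c1 == c2)
            bad = testable & (c1 != u1)
            loci_tested += int(testable.sum())
            for j in np.flatnonzero(bad):
                violations.append(
                    Violation(
                        child,
                        marker_names[j],
                        c1[j] + c2[j],
                        (u1[j] + u2[j],),
                        "single_parent",
                    )
                )
    for v in violations:
        per_line[v.child] = per_line.get(v.child, 0) + 1
    het = {line: matrix.heterozygosity(line) for line in shared}
    return ConsistencyReport(violations, per_line, loci_tested, trios, het)


# ---------------------------------------------------------------------------
# Matching and parent inference


def match_genotype(
    query: Sequence[str], matrix: GenotypeMatrix, top_k: int = 10, min_loci: int = 1
) -> list[tuple[str, float, int]]:
    """Rank matrix lines by similarity to a query call vector.

    The query must be aligned to the matrix markers.  Returns up to
    ``top_k`` of ``(line, percent, n_loci)``, best first; an all-missing
    query matches nothing.
    """
    if len(query) != matrix.n_markers:
        raise PednetError(
            f"query has {len(query)} calls, matrix has {matrix.n_markers} markers"
        )
    calls = [normalise_call(c) if c else MISSING for c in query]
    qa1 = np.array([c[0] if c else "" for c in calls], dtype="<U1")
    qa2 = np.array([c[1] if c else "" for c in calls], dtype="<U1")
    scored = []
    for i, line in enumerate(matrix.lines):
        out = _row_similarity(matrix, qa1, qa2, i)
        if out is not None and out[1] >= min_loci:
            scored.append((line, out[0], out[1]))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:top_k]


def infer_second_parent(
    net: PedigreeNet,
    matrix: GenotypeMatrix,
    child: str,
    known_parent: str,
    top_k: int = 10,
) -> list[tuple[str, float, int]]:
    """Rank candidate second parents of ``child`` given one known parent.

    Every other genotyped line is scored by the fraction of testable loci
    where the trio (child, known_parent, candidate) passes the union rule.
    The child itself and its descendants are excluded (a descendant can
    never be a parent).  Returns ``(line, consistent_fraction, n_testable)``
    sorted by fraction, then name.
    """
    if child not in matrix:
        raise PednetError(f"child {child!r} is not genotyped")
    if known_parent not in matrix:
        raise PednetError(f"known parent {known_parent!r} is not genotyped")
    excluded = {child}
    if child in net:
        excluded |= net.descendants(child)
    ci = matrix.row_index(child)
    pi = matrix.row_index(known_parent)
    c1, c2 = matrix.a1[ci], matrix.a2[ci]
    u1, u2 = matrix.a1[pi], matrix.a2[pi]
    base_testable = (c1 != "") & (u1 != "")
    from_known_1 = (c1 == u1) | (c1 == u2)
    from_known_2 = (c2 == u1) | (c2 == u2)
    results = []
    for i, line in enumerate(matrix.lines):
        if line in excluded:
            continue
        v1, v2 = matrix.a1[i], matrix.a2[i]
        testable = base_testable & (v1 != "")
        n = int(testable.sum())
        if n == 0:
            continue
        ok1 = from_known_1 | (c1 == v1) | (c1 == v2)
        ok2 = from_known_2 | (c2 == v1) | (c2 == v2)
        consistent = int((testable & ok1 & ok2).sum())
        results.append((line, consistent / n, n))
    results.sort(key=lambda item: (-item[1], item[0]))
    return results[:top_k]
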