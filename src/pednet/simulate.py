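"""Synthetic breeding programmes with known ground truth.

The generator emulates the shape of an elite inbred cereal panel: a pool of
homozygous founders, a sequence of crosses each yielding one named inbred
(doubled-haploid-like) descendant, occasional selfing, and the pedigree-net
signature of crop breeding — old founders and varieties re-entering modern
crosses, producing edges that span several generations.  Genotypes are
biallelic SNPs; each derived line fixes one parental allele per locus,
except for a small residual-heterozygosity rate (default 0.4%, matching
the sub-0.5% levels typical of elite inbred panels).  Nominal and ordinal
DUS-like traits are inherited with a parent bias so phenotype overlays
show visible structure.

Everything is deterministic per seed, and controlled corruptions
(:func:`inject_genotype_errors`, :func:`inject_swap`) come with an exact
truth list, so detection tests can be sharp rather than statistical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import GenotypeMatrix, Marker, write_genotypes
from .net import PedigreeNet, build_net
from .notation import ParentChildRecord
from .overlay import PhenotypeTable, write_phenotypes
from .io import write_pedigree_table

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "InjectedError",
    "simulate_breeding_program",
    "inject_genotype_errors",
    "inject_swap",
    "elite_panel_config",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: name, nominal/ordinal kind and its classes."""

    name: str
    kind: str
    classes: tuple[str, ...]


DEFAULT_TRAITS = (
    TraitSpec("ecotype", "nominal", ("spring", "winter")),
    TraitSpec("row_type", "nominal", ("2-row", "6-row")),
    TraitSpec("anthocyanin_colour", "ordinal", ("1", "2", "3", "4", "5")),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated breeding programme.

    ``p_old_parent`` is the probability that a cross reaches back to a line
    at least three generations older than the current front, producing the
    long cross-generation edges characteristic of pedigree nets;
    ``residual_het_rate`` is the per-locus chance a derived line stays
    heterozygous; ``selfing_rate`` the chance one parent fills both roles.
    """

    n_founders: int = 40
    n_crosses: int = 160
    n_markers: int = 1000
    p_old_parent: float = 0.15
    residual_het_rate: float = 0.004
    selfing_rate: float = 0.02
    genotyped_fraction: float = 1.0
    phenotype_bias: float = 0.8
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1 or self.n_markers < 1 or self.n_crosses < 0:
            raise ValueError("counts must be positive")
        for name in (
            "p_old_parent",
            "residual_het_rate",
            "selfing_rate",
            "genotyped_fraction",
            "phenotype_bias",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def elite_panel_config(seed: int = 0) -> SimConfig:
    """Preset mirroring the shape of a national elite barley panel:
    803 lines in total, 4,769 SNP markers, genotypes for 750 of the lines,
    and 33 DUS-style traits."""
    traits = []
    for t in range(33):
        if t % 2 == 0:
            k = 2 + t % 5
            traits.append(
                TraitSpec(f"dus_{t + 1:02d}", "nominal", tuple(f"c{j}" for j in range(1, k + 1)))
            )
        else:
            k = 3 + t % 7
            traits.append(
                TraitSpec(f"dus_{t + 1:02d}", "ordinal", tuple(str(j) for j in range(1, k + 1)))
            )
    return SimConfig(
        n_founders=100,
        n_crosses=703,
        n_markers=4769,
        genotyped_fraction=750 / 803,
        traits=tuple(traits),
        seed=seed,
    )


@dataclass(frozen=True)
class InjectedError:
    line: str
    marker: str
    original_call: str
    corrupted_call: str


@dataclass
class SimTruth:
    """A simulated programme plus the ground truth needed to audit it."""

    config: SimConfig
    records: list[ParentChildRecord]
    net: PedigreeNet
    matrix: GenotypeMatrix
    phenotypes: list[PhenotypeTable]
    generations: dict[str, int]
    injected_errors: list[InjectedError] = field(default_factory=list)
    swaps: list[tuple[str, str]] = field(default_factory=list)


def _founder_name(i: int) -> str:
    return f"F{i + 1:03d}"


def _cross_name(i: int) -> str:
    return f"C{i + 1:03d}"


def simulate_breeding_program(config: SimConfig) -> SimTruth:
    """Generate a full programme: pedigree net, genotypes, phenotypes.

    Parent choice drives the net topology: the female parent is drawn from
    recently created lines (keeping the programme moving forward), while
    the male parent reaches back to the old pool (lines at least three
    generations above the front) with probability ``p_old_parent``.  Child
    genotypes always satisfy the Mendelian union rule by construction, so a
    clean simulation yields zero violations.
    """
    rng = np.random.default_rng(config.seed)
    n_f, n_c, n_m = config.n_founders, config.n_crosses, config.n_markers

    # marker definitions: two distinct alleles per biallelic SNP
    first = rng.integers(0, 4, size=n_m)
    offset = rng.integers(1, 4, size=n_m)
    allele_a = _BASES[first]
    allele_b = _BASES[(first + offset) % 4]
    markers = [
        Marker(f"M{j + 1:05d}", chromosome=str(1 + j % 7), position=float(j))
        for j in range(n_m)
    ]

    names: list[str] = [_founder_name(i) for i in range(n_f)]
    total = n_f + n_c
    a1 = np.full((total, n_m), "", dtype="<U1")
    a2 = np.full((total, n_m), "", dtype="<U1")
    pick_b = rng.random((n_f, n_m)) < 0.5
    founder_calls = np.where(pick_b, allele_b, allele_a)
    a1[:n_f] = founder_calls
    a2[:n_f] = founder_calls

    layers = {name: 0 for name in names}
    records: list[ParentChildRecord] = [ParentChildRecord(name) for name in names]
    index = {name: i for i, name in enumerate(names)}

    for c in range(n_c):
        child = _cross_name(c)
        existing = names
        # female parent from the recent end of the programme
        recent = existing[-min(10, len(existing)) :]
        p1 = recent[rng.integers(0, len(recent))]
        if rng.random() < config.selfing_rate:
            p2 = p1
        else:
            front = max(layers.values())
            old_pool = [n for n in existing if layers[n] <= front - 3]
            if old_pool and rng.random() < config.p_old_parent:
                p2 = old_pool[rng.integers(0, len(old_pool))]
            else:
                p2 = existing[rng.integers(0, len(existing))]
        records.append(ParentChildRecord(child, p1, p2))
        layers[child] = 1 + max(layers[p1], layers[p2])

        # one gamete allele from each parent, then fix to a homozygote
        # (or keep the heterozygote at the residual rate)
        i1, i2 = index[p1], index[p2]
        g1 = np.where(rng.random(n_m) < 0.5, a1[i1], a2[i1])
        g2 = np.where(rng.random(n_m) < 0.5, a1[i2], a2[i2])
        fixed = np.where(rng.random(n_m) < 0.5, g1, g2)
        het = (rng.random(n_m) < config.residual_het_rate) & (g1 != g2)
        lo = np.where(g1 < g2, g1, g2)
        hi = np.where(g1 < g2, g2, g1)
        row = len(names)
        a1[row] = np.where(het, lo, fixed)
        a2[row] = np.where(het, hi, fixed)
        names.append(child)
        index[child] = row

    net = build_net(records)

    if config.genotyped_fraction < 1.0:
        n_geno = int(round(config.genotyped_fraction * total))
        keep = np.sort(rng.choice(total, size=n_geno, replace=False))
    else:
        keep = np.arange(total)
    matrix = GenotypeMatrix.from_allele_arrays(
        [names[i] for i in keep], markers, a1[keep], a2[keep]
    )

    phenotypes = _simulate_phenotypes(config, names, records, rng)
    return SimTruth(config, records, net, matrix, phenotypes, dict(layers))


def _simulate_phenotypes(
    config: SimConfig,
    names: list[str],
    records: list[ParentChildRecord],
    rng: np.random.Generator,
) -> list[PhenotypeTable]:
    parent_of = {r.child: (r.parent_1, r.parent_2) for r in records}
    tables = []
    for spec in config.traits:
        classes = list(spec.classes)
        values: dict[str, str] = {}
        for name in names:
            p1, p2 = parent_of.get(name, (None, None))
            if p1 is not None and rng.random() < config.phenotype_bias:
                donor = p1 if p2 is None or rng.random() < 0.5 else p2
                values[name] = values[donor]
            else:
                values[name] = classes[rng.integers(0, len(classes))]
        tables.append(
            PhenotypeTable(
                spec.name,
                spec.kind,
                values,
                tuple(classes) if spec.kind == "ordinal" else None,
            )
        )
    return tables


def inject_genotype_errors(truth: SimTruth, n_errors: int, seed: int = 0) -> SimTruth:
    """Corrupt ``n_errors`` distinct calls of two-genotyped-parent children.

    Each corrupted call becomes a homozygote of an allele *outside* the
    parental union at that locus, so every injected error breaks the union
    rule and is detectable by :func:`pednet.genetics.check_mendelian`.
    The corruptions are recorded in the returned truth.
    """
    rng = np.random.default_rng(seed)
    matrix = truth.matrix
    eligible = []
    for child in truth.net.lines:
        if child not in matrix:
            continue
        parents = truth.net.parents(child)
        if len(parents) != 2 or any(p not in matrix for p in parents):
            continue
        ci = matrix.row_index(child)
        called = np.flatnonzero(matrix.a1[ci] != "")
        eligible.extend((child, int(j)) for j in called)
    if n_errors > len(eligible):
        raise ValueError(
            f"cannot inject {n_errors} errors: only {len(eligible)} eligible cells"
        )
    if n_errors == 0:
        return truth
    chosen = rng.choice(len(eligible), size=n_errors, replace=False)
    a1 = matrix.a1.copy()
    a2 = matrix.a2.copy()
    errors = list(truth.injected_errors)
    for k in sorted(int(c) for c in chosen):
        child, j = eligible[k]
        ci = matrix.row_index(child)
        union = set()
        for p in truth.net.parents(child):
            pi = matrix.row_index(p)
            union |= {matrix.a1[pi, j], matrix.a2[pi, j]}
        outside = sorted(set("ACGT") - union)
        allele = outside[rng.integers(0, len(outside))]
        original = matrix.a1[ci, j] + matrix.a2[ci, j]
        a1[ci, j] = allele
        a2[ci, j] = allele
        errors.append(
            InjectedError(child, matrix.markers[j].name, original, allele + allele)
        )
    corrupted = GenotypeMatrix.from_allele_arrays(
        matrix.lines, matrix.markers, a1, a2
    )
    return dataclasses.replace(truth, matrix=corrupted, injected_errors=errors)


def inject_swap(truth: SimTruth, line_a: str, line_b: str) -> SimTruth:
    """Swap the genotype rows of two lines (a sample mislabelling), leaving
    the pedigree untouched.  Swapping the same pair twice is the identity."""
    matrix = truth.matrix
    i = matrix.row_index(line_a)
    j = matrix.row_index(line_b)
    a1 = matrix.a1.copy()
    a2 = matrix.a2.copy()
    a1[[i, j]] = a1[[j, i]]
    a2[[i, j]] = a2[[j, i]]
    swapped = GenotypeMatrix.from_allele_arrays(matrix.lines, matrix.markers, a1, a2)
    return dataclasses.replace(
        truth, matrix=swapped, swaps=truth.swaps + [(line_a, line_b)]
    )


def write_dataset(truth: SimTruth, directory: str | Path) -> dict[str, Path]:
    """Write the programme to disk in the toolkit's file formats.

    Emits pedigree.csv, genotypes.tsv, markers.tsv, phenotypes.csv,
    traits.csv, truth_errors.tsv and manifest.json; returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": directory / "pedigree.csv",
        "genotypes": directory / "genotypes.tsv",
        "markers": directory / "markers.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "traits": directory / "traits.csv",
        "truth_errors": directory / "truth_errors.tsv",
        "manifest": directory / "manifest.json",
    }
    with open(paths["pedigree"], "w") as fh:
        write_pedigree_table(truth.records, fh)
    with open(paths["genotypes"], "w") as geno, open(paths["markers"], "w") as mp:
        write_genotypes(truth.matrix, geno, mp)
    with open(paths["phenotypes"], "w") as ph, open(paths["traits"], "w") as tr:
        write_phenotypes(truth.phenotypes, ph, tr)
    with open(paths["truth_errors"], "w") as fh:
        fh.write("line\tmarker\toriginal_call\tcorrupted_call\n")
        for err in truth.injected_errors:
            fh.write(
                f"{err.line}\t{err.marker}\t{err.original_call}\t{err.corrupted_call}\n"
            )
        for a, b in truth.swaps:
            fh.write(f"{a}\t*\tswapped_with:{b}\t\n")
    config = dataclasses.asdict(truth.config)
    config["traits"] = [dataclasses.asdict(t) for t in truth.config.traits]
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "config": config,
                "n_lines": len(truth.net),
                "n_genotyped": truth.matrix.n_lines,
                "n_markers": truth.matrix.n_markers,
                "n_injected_errors": len(truth.injected_errors),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
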