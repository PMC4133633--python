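"""Visual encodings for phenotype and usage data.

Nominal trait classes (ecotype, row number, ...) are distinguished by hue
with a qualitative palette; ordinal classes (most DUS scoring scales) by a
saturation ramp at a single hue, so the class order reads as colour
intensity.  Human colour discrimination degrades beyond about eight
classes, so both scales raise an ``overflow_flag`` past that point rather
than refusing to render.  Node size encodes how often a line was used as a
parent, with area roughly proportional to usage.
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import PednetError, PedigreeFormatError
from .net import PedigreeNet

__all__ = [
    "PhenotypeTable",
    "ColorScale",
    "NodeStyle",
    "nominal_scale",
    "ordinal_scale",
    "merge_phenotypes",
    "size_nodes",
    "colour_nodes",
    "make_styles",
    "histogram",
    "read_phenotypes",
    "write_phenotypes",
]

#: Perceptual class-count limit before colours stop being distinguishable.
CLASS_LIMIT = 8

#: Embedded qualitative palette (ColorBrewer Paired, 12 classes) so output
#: is reproducible without any runtime palette dependency.
QUALITATIVE_12 = (
    "#A6CEE3", "#1F78B4", "#B2DF8A", "#33A02C", "#FB9A99", "#E31A1C",
    "#FDBF6F", "#FF7F00", "#CAB2D6", "#6A3D9A", "#FFFF99", "#B15928",
)

#: Colour for lines with no phenotype record: visually recessive grey.
MISSING_COLOR = "#BDBDBD"

_ORDINAL_HUE = 0.58  # blue
_ORDINAL_VALUE = 0.85


@dataclass
class PhenotypeTable:
    """One trait's class labels per line.

    ``kind`` is ``nominal`` or ``ordinal``; ordinal tables carry an explicit
    total order over their classes.  Missing lines are simply absent from
    ``values``.
    """

    trait: str
    kind: str
    values: dict[str, str]
    class_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordinal"):
            raise ValueError(f"kind must be nominal or ordinal, got {self.kind!r}")
        if self.kind == "ordinal":
            if not self.class_order:
                raise ValueError("ordinal table requires an explicit class order")
            if len(set(self.class_order)) != len(self.class_order):
                raise ValueError("ordinal class order contains duplicates")

    def classes(self) -> list[str]:
        if self.kind == "ordinal":
            return list(self.class_order)  # type: ignore[arg-type]
        return sorted(set(self.values.values()))


@dataclass
class ColorScale:
    """Mapping from class label to sRGB hex colour."""

    mapping: dict[str, str]
    kind: str
    overflow_flag: bool = False

    def __getitem__(self, label: str) -> str:
        return self.mapping[label]

    def __contains__(self, label: str) -> bool:
        return label in self.mapping


@dataclass(frozen=True)
class NodeStyle:
    color: str = MISSING_COLOR
    size: float = 6.0


def _hex(rgb: tuple[float, float, float]) -> str:
    return "#{:02X}{:02X}{:02X}".format(
        *(int(round(channel * 255)) for channel in rgb)
    )


def _lighten(hex_color: str, amount: float) -> str:
    r = int(hex_color[1:3], 16) / 255
    g = int(hex_color[3:5], 16) / 255
    b = int(hex_color[5:7], 16) / 255
    return _hex(tuple(c + (1 - c) * amount for c in (r, g, b)))


def nominal_scale(classes: Iterable[str]) -> ColorScale:
    """Qualitative (distinct-hue) colour scale for nominal classes.

    Classes are assigned palette colours in sorted label order.  More than
    :data:`CLASS_LIMIT` classes sets ``overflow_flag``; beyond the 12-colour
    palette, colours cycle with a progressive lightness shift so every class
    still gets its own colour.
    """
    labels = sorted(set(classes))
    if not labels:
        raise PednetError("nominal scale requires at least one class")
    mapping: dict[str, str] = {}
    for i, label in enumerate(labels):
        base = QUALITATIVE_12[i % len(QUALITATIVE_12)]
        cycle = i // len(QUALITATIVE_12)
        mapping[label] = _lighten(base, 0.25 * cycle) if cycle else base
    return ColorScale(mapping, "nominal", overflow_flag=len(labels) > CLASS_LIMIT)


def ordinal_scale(ordered_classes: Sequence[str]) -> ColorScale:
    """Saturation-ramp colour scale for ordered classes at a fixed hue.

    Saturation increases strictly monotonically from the first class to the
    last; a single class gets a mid-saturation colour.
    """
    labels = list(ordered_classes)
    if not labels:
        raise PednetError("ordinal scale requires at least one class")
    if len(set(labels)) != len(labels):
        raise PednetError("ordinal class order contains duplicate classes")
    lo, hi = 0.15, 0.95
    if len(labels) == 1:
        sats = [0.55]
    else:
        sats = [lo + (hi - lo) * i / (len(labels) - 1) for i in range(len(labels))]
    mapping = {
        label: _hex(colorsys.hsv_to_rgb(_ORDINAL_HUE, s, _ORDINAL_VALUE))
        for label, s in zip(labels, sats)
    }
    return ColorScale(mapping, "ordinal", overflow_flag=len(labels) > CLASS_LIMIT)


def merge_phenotypes(tables: Sequence[PhenotypeTable]) -> PhenotypeTable:
    """Combine several traits into one nominal trait of exact combinations.

    Each line's combined class is its per-trait labels joined with ``|``;
    a line missing any of the traits gets class ``missing``.  The result is
    nominal: users look for exact combinations, rendered as a single node
    colour.  Combined class counts grow multiplicatively (around 20 is
    common with two or three traits), so the downstream nominal scale will
    typically flag overflow.
    """
    if not tables:
        raise PednetError("merge_phenotypes requires at least one table")
    lines: set[str] = set()
    for table in tables:
        lines |= set(table.values)
    values = {}
    for line in lines:
        labels = [table.values.get(line) for table in tables]
        values[line] = (
            "missing" if any(v is None for v in labels) else "|".join(labels)
        )
    name = "+".join(table.trait for table in tables)
    return PhenotypeTable(name, "nominal", values)


def size_nodes(
    net: PedigreeNet, s_min: float = 4.0, s_max: float = 16.0
) -> dict[str, float]:
    """Node radii from parental usage: ``s_min + (s_max-s_min)*sqrt(u/u_max)``.

    The square root makes node *area* roughly linear in usage, so heavily
    used parents dominate visually in proportion to their contribution.
    """
    if s_min >= s_max:
        raise ValueError("s_min must be < s_max")
    usages = {line: net.usage_count(line) for line in net.lines}
    u_max = max(usages.values(), default=0)
    if u_max == 0:
        return {line: s_min for line in usages}
    return {
        line: s_min + (s_max - s_min) * (u / u_max) ** 0.5
        for line, u in usages.items()
    }


def colour_nodes(
    net: PedigreeNet, table: PhenotypeTable, scale: ColorScale
) -> dict[str, str]:
    """Colour every line by its class; lines without a value get grey."""
    colors = {}
    for line in net.lines:
        label = table.values.get(line)
        if label is None:
            colors[line] = MISSING_COLOR
        elif label not in scale:
            raise PednetError(
                f"class {label!r} of line {line!r} missing from colour scale"
            )
        else:
            colors[line] = scale[label]
    return colors


def make_styles(
    net: PedigreeNet,
    colors: dict[str, str] | None = None,
    sizes: dict[str, float] | None = None,
) -> dict[str, NodeStyle]:
    """Combine colour and size maps into a per-line style map."""
    default = NodeStyle()
    return {
        line: NodeStyle(
            color=(colors or {}).get(line, default.color),
            size=(sizes or {}).get(line, default.size),
        )
        for line in net.lines
    }


def histogram(
    values: Sequence[float],
    bins: int = 11,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram (right-open bins, last bin closed).

    Returns ``(counts, edges)``; counts over in-range values sum to the
    number of in-range values.  Used for the similarity-distribution
    summary shown next to cutoff queries.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise PednetError("histogram requires at least one value")
    return np.histogram(values, bins=bins, range=value_range)


# ---------------------------------------------------------------------------
# Phenotype file formats: long CSV `line,trait,value` plus a metadata CSV
# `trait,kind,class_order` (order classes joined with ';').


def read_phenotypes(stream: IO[str], meta_stream: IO[str]) -> list[PhenotypeTable]:
    meta: dict[str, tuple[str, tuple[str, ...] | None]] = {}
    reader = csv.reader(meta_stream)
    header = next(reader, None)
    if header is None:
        raise PedigreeFormatError("empty trait metadata file")
    for row in reader:
        if not row or not any(c.strip() for c in row):
            continue
        trait = row[0].strip()
        kind = row[1].strip().lower()
        order = tuple(c.strip() for c in row[2].split(";") if c.strip()) if len(row) > 2 and row[2].strip() else None
        meta[trait] = (kind, order)
    values: dict[str, dict[str, str]] = {}
    reader = csv.reader(stream)
    header = next(reader, None)
    if header is None:
        raise PedigreeFormatError("empty phenotype file")
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(c.strip() for c in row):
            continue
        if len(row) < 3:
            raise PedigreeFormatError(f"row {lineno}: expected line,trait,value")
        line, trait, value = (c.strip() for c in row[:3])
        if value:
            values.setdefault(trait, {})[line] = value
    tables = []
    for trait in sorted(values):
        kind, order = meta.get(trait, ("nominal", None))
        tables.append(PhenotypeTable(trait, kind, values[trait], order))
    return tables


def write_phenotypes(
    tables: Sequence[PhenotypeTable], stream: IO[str], meta_stream: IO[str]
) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["line", "trait", "value"])
    for table in tables:
        for line in sorted(table.values):
            writer.writerow([line, table.trait, table.values[line]])
    meta_writer = csv.writer(meta_stream, lineterminator="\n")
    meta_writer.writerow(["trait", "kind", "class_order"])
    for table in tables:
        order = ";".join(table.class_order) if table.class_order else ""
        meta_writer.writerow([table.trait, table.kind, order])
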