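"""Readers and writers for the toolkit's file formats.

* pedigree-notation text: one ``name<TAB>pedigree_string`` per row, ``#``
  comments and blank lines ignored;
* atomised pedigree CSV: ``child,parent_1,parent_2[,cross_type]``;
* GraphViz dot and a JSON graph document for downstream rendering.

All writers emit deterministically ordered, byte-stable output.
"""

from __future__ import annotations

import csv
import json
import warnings
from typing import IO, Iterable

from .errors import PedigreeFormatError, UnknownLineError
from .net import PedigreeNet, classify_lines
from .notation import (
    CrossTree,
    ParentChildRecord,
    atomise,
    cross,
    founder,
    parse_pedigree_string,
    serialize_purdy_tree,
)

__all__ = [
    "read_notation_file",
    "read_pedigree_table",
    "write_pedigree_table",
    "serialize_purdy",
    "write_dot",
    "write_graph_json",
]


def read_notation_file(
    stream: IO[str], dialect: str = "auto"
) -> list[ParentChildRecord]:
    """Parse and atomise a pedigree-notation file.

    Each data row is ``name<TAB>pedigree_string``; a row with no tab is a
    bare founder declaration.  Parse failures are re-raised with the row
    number attached.
    """
    records: list[ParentChildRecord] = []
    seen: set[tuple] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, _, text = line.partition("\t")
        name = name.strip()
        text = text.strip()
        if not text:
            records.append(ParentChildRecord(name))
            continue
        try:
            tree = parse_pedigree_string(text, dialect=dialect)
        except Exception as exc:
            raise PedigreeFormatError(f"row {lineno}: {exc}") from exc
        if tree.is_founder and tree.name != name:
            # "X <TAB> A" records X as a renamed selection from A; treat as
            # single-parent derivation
            records.append(ParentChildRecord(name, tree.name))
        else:
            for rec in atomise(name, tree) or [ParentChildRecord(name)]:
                key = (rec.child, rec.parent_1, rec.parent_2)
                if key not in seen:
                    seen.add(key)
                    records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Pedigree CSV

_HEADER = ["child", "parent_1", "parent_2"]


def read_pedigree_table(stream: IO[str]) -> list[ParentChildRecord]:
    """Read an atomised pedigree CSV (``child,parent_1,parent_2[,cross_type]``).

    Empty parent cells mean unknown; a row with ``parent_2`` but no
    ``parent_1`` is malformed.  Exact duplicate rows are dropped with a
    warning.
    """
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise PedigreeFormatError("empty pedigree file: header row required")
    header = [h.strip().lower() for h in header]
    if header[:3] != _HEADER:
        raise PedigreeFormatError(
            f"expected header child,parent_1,parent_2[,cross_type], got {header}"
        )
    has_type = len(header) > 3 and header[3] == "cross_type"
    records: list[ParentChildRecord] = []
    seen: set[tuple] = set()
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        cells = [cell.strip() for cell in row] + [""] * (4 - len(row))
        child, p1, p2 = cells[0], cells[1] or None, cells[2] or None
        if not child:
            raise PedigreeFormatError(f"row {lineno}: empty child name")
        if p2 is not None and p1 is None:
            raise PedigreeFormatError(
                f"row {lineno}: parent_2 given without parent_1"
            )
        key = (child, p1, p2)
        if key in seen:
            warnings.warn(
                f"row {lineno}: duplicate record {key} dropped", stacklevel=2
            )
            continue
        seen.add(key)
        records.append(
            ParentChildRecord(child, p1, p2, cells[3] or None if has_type else None)
        )
    return records


def write_pedigree_table(records: Iterable[ParentChildRecord], stream: IO[str]) -> int:
    """Write records back to pedigree CSV; returns the row count."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(_HEADER + ["cross_type"])
    n = 0
    for rec in records:
        writer.writerow(
            [rec.child, rec.parent_1 or "", rec.parent_2 or "", rec.cross_type or ""]
        )
        n += 1
    return n


# ---------------------------------------------------------------------------
# Purdy serialisation from a net


def serialize_purdy(net: PedigreeNet, line: str) -> str:
    """Serialise the full ancestry of ``line`` to a strict Purdy string.

    The net's ancestor DAG is unfolded into a tree (shared ancestors are
    repeated, as pedigree strings require); parsing the result back and
    atomising reconstructs a net isomorphic to the ancestor sub-net.
    """
    if line not in net:
        raise UnknownLineError(f"unknown line {line!r}")

    def expand(name: str) -> CrossTree:
        parents = net.parents(name)
        if not parents:
            return founder(name)
        p1, p2 = net.parent_roles(name)
        if p2 is None:
            return expand(p1)  # single-parent derivation collapses
        return cross(expand(p1), expand(p2))

    tree = expand(line)
    return serialize_purdy_tree(tree)


# ---------------------------------------------------------------------------
# GraphViz dot


def _quote(name: str) -> str:
    return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_dot(net: PedigreeNet, styles: dict | None = None) -> str:
    """Emit the net as GraphViz dot text.

    One node statement per line (with ``fillcolor`` and ``width`` when a
    style map is given), one directed edge per parent role — a selfing
    appears as two parallel edges.  Output is sorted, hence byte-stable.
    """
    out = ["digraph pedigree {", "  rankdir=TB;", "  node [shape=circle];"]
    for name in net.lines:
        attrs = []
        if styles and name in styles:
            style = styles[name]
            attrs.append('style=filled')
            attrs.append(f'fillcolor="{style.color}"')
            attrs.append(f"width={style.size:.3f}")
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        out.append(f"  {_quote(name)}{suffix};")
    for parent, child, role in sorted(net.edges()):
        out.append(f'  {_quote(parent)} -> {_quote(child)} [role="{role}"];')
    out.append("}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Graph JSON


def write_graph_json(net: PedigreeNet, layout=None, styles: dict | None = None) -> str:
    """Serialise the net (plus optional layout and styles) to a JSON graph.

    Schema: ``{"nodes": [{"id", "layer", "x", "size", "color", "role"}, ...],
    "edges": [{"from", "to", "route": [[x, layer], ...]}, ...]}``.  ``layer``,
    ``x`` and ``route`` appear only when a layout is given; ``size``/``color``
    only with styles.  Keys are sorted for stable output.
    """
    roles = classify_lines(net)
    nodes = []
    for name in net.lines:
        node: dict = {"id": name, "role": roles[name]}
        if layout is not None:
            if name not in layout.positions:
                raise PedigreeFormatError(f"layout is missing node {name!r}")
            x, layer = layout.positions[name]
            node["x"] = round(x, 3)
            node["layer"] = layer
        if styles and name in styles:
            node["color"] = styles[name].color
            node["size"] = round(styles[name].size, 3)
        nodes.append(node)
    edges = []
    for parent, child, role in sorted(net.edges()):
        edge: dict = {"from": parent, "to": child, "parent_role": role}
        if layout is not None:
            route = layout.edge_route(parent, child, role)
            edge["route"] = [[round(x, 3), layer] for x, layer in route]
        edges.append(edge)
    return json.dumps({"edges": edges, "nodes": nodes}, sort_keys=True, indent=2)
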