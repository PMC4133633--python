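"""Parsing and serialisation of plant-cross pedigree notation.

Two dialects are supported:

* **Purdy** notation, the slash-delimited shorthand used for small-grain
  cereal crosses.  ``A/B`` is the cross of A and B; deeper separators mark
  later crosses, so ``A/B//C/3/D`` reads "A crossed with B, the progeny
  crossed with C, that progeny crossed with D".  Separators are ``/``,
  ``//`` and the numeric form ``/n/`` for n >= 3.  Historical records are
  rarely strict: repeated equal-order separators (``A/B//C//D``) are read
  left-associatively, which matches the conventional reading.

* **Lamacraft–Finlay** notation, a parenthesised infix form designed for
  machine parsing: ``((A * B) * C) * D``.  ``×`` is accepted as a synonym
  for ``*`` and square brackets as synonyms for round ones, because mixed
  bracket styles are common in old breeders' records.

A parsed pedigree is a binary :class:`CrossTree` whose leaves are named
founder lines and whose internal nodes are crosses.  The left subtree is
the female parent by convention (the notation itself does not encode sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PedigreeParseError

__all__ = [
    "CrossTree",
    "ParentChildRecord",
    "parse_purdy",
    "parse_lamacraft",
    "parse_pedigree_string",
    "serialize_purdy_tree",
    "atomise",
    "trees_isomorphic",
]


@dataclass(frozen=True)
class CrossTree:
    """Binary parse tree of a pedigree string.

    ``kind`` is ``"founder"`` (leaf, non-empty ``name``) or ``"cross"``
    (exactly two subtrees; the two sides may name the same line, which is a
    selfing).
    """

    kind: str
    name: str = ""
    left: "CrossTree | None" = None
    right: "CrossTree | None" = None
    cross_type: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "founder":
            if not self.name:
                raise ValueError("founder node requires a non-empty name")
            if self.left is not None or self.right is not None:
                raise ValueError("founder node cannot have subtrees")
        elif self.kind == "cross":
            if self.left is None or self.right is None:
                raise ValueError("cross node requires two subtrees")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    @property
    def is_founder(self) -> bool:
        return self.kind == "founder"

    def founders(self) -> list[str]:
        """Distinct founder names, in first-appearance (left-to-right) order."""
        seen: dict[str, None] = {}

        def walk(node: CrossTree) -> None:
            if node.is_founder:
                seen.setdefault(node.name, None)
            else:
                walk(node.left)  # type: ignore[arg-type]
                walk(node.right)  # type: ignore[arg-type]

        walk(self)
        return list(seen)

    def cross_count(self) -> int:
        if self.is_founder:
            return 0
        return 1 + self.left.cross_count() + self.right.cross_count()  # type: ignore[union-attr]


def founder(name: str) -> CrossTree:
    return CrossTree("founder", name=name)


def cross(left: CrossTree, right: CrossTree, cross_type: str | None = None) -> CrossTree:
    return CrossTree("cross", left=left, right=right, cross_type=cross_type)


@dataclass(frozen=True)
class ParentChildRecord:
    """Elementary (child, parent_1, parent_2) pedigree definition.

    ``parent_1`` may equal ``parent_2`` (selfing: one line serves both
    parental roles).  A founder row carries no parents at all.
    """

    child: str
    parent_1: str | None = None
    parent_2: str | None = None
    cross_type: str | None = None

    def __post_init__(self) -> None:
        if not self.child:
            raise ValueError("child name must be non-empty")
        if self.parent_2 is not None and self.parent_1 is None:
            raise ValueError("parent_2 given without parent_1")


# ---------------------------------------------------------------------------
# Purdy notation


def _tokenize_purdy(text: str) -> tuple[list[tuple[str, int]], list[tuple[int, int]]]:
    """Split a Purdy string into operands and separators.

    Returns ``(operands, separators)`` where operands are ``(name, offset)``
    and separators are ``(order, offset)``; there is always one more operand
    than separator.  Operands may be empty strings (validated by the caller
    so the error can report the precise offset).
    """
    operands: list[tuple[str, int]] = []
    seps: list[tuple[int, int]] = []
    i = 0
    start = 0
    n = len(text)
    while i < n:
        if text[i] != "/":
            i += 1
            continue
        operands.append((text[start:i], start))
        # numeric form /k/ (k >= 3, possibly multi-digit)
        j = i + 1
        while j < n and text[j].isdigit():
            j += 1
        if j > i + 1 and j < n and text[j] == "/":
            order = int(text[i + 1 : j])
            if order < 3:
                raise PedigreeParseError(
                    f"numeric separator /{order}/ must have order >= 3", offset=i
                )
            seps.append((order, i))
            i = j + 1
        else:
            run = i
            while i < n and text[i] == "/":
                i += 1
            seps.append((i - run, run))
        start = i
    operands.append((text[start:], start))
    return operands, seps


def parse_purdy(text: str) -> CrossTree:
    """Parse a Purdy-notation pedigree string into a :class:`CrossTree`.

    Splitting happens at the highest-order separator present; repeated
    equal-order separators associate left, so ``A/B//C//D`` parses as
    ``((A x B) x C) x D``.
    """
    if not text or not text.strip():
        raise PedigreeParseError("empty pedigree string", offset=0)
    operands, seps = _tokenize_purdy(text)
    for name, off in operands:
        if not name.strip():
            if seps:  # a bare empty string was caught above
                raise PedigreeParseError("empty operand between separators", offset=off)
            raise PedigreeParseError("empty pedigree string", offset=off)
    return _parse_purdy_range(operands, seps, 0, len(operands) - 1)


def _parse_purdy_range(
    operands: list[tuple[str, int]],
    seps: list[tuple[int, int]],
    lo: int,
    hi: int,
) -> CrossTree:
    """Parse operands[lo..hi] joined by seps[lo..hi-1] (inclusive slices)."""
    if lo == hi:
        return founder(operands[lo][0].strip())
    window = range(lo, hi)
    top = max(seps[k][0] for k in window)
    # left association: split at the *last* occurrence of the top order
    split = max(k for k in window if seps[k][0] == top)
    left = _parse_purdy_range(operands, seps, lo, split)
    right = _parse_purdy_range(operands, seps, split + 1, hi)
    return cross(left, right)


# ---------------------------------------------------------------------------
# Lamacraft–Finlay notation

_LF_OPEN = "(["
_LF_CLOSE = ")]"
_LF_STARS = "*×"


def parse_lamacraft(text: str) -> CrossTree:
    """Parse Lamacraft–Finlay (parenthesised ``*``) notation.

    Unparenthesised chains associate left: ``A * B * C`` is ``(A x B) x C``.
    ``×`` ≡ ``*`` and ``[`` ``]`` ≡ ``(`` ``)``.
    """
    if not text or not text.strip():
        raise PedigreeParseError("empty pedigree string", offset=0)
    norm = []
    for ch in text:
        if ch in _LF_STARS:
            norm.append("*")
        elif ch in _LF_OPEN:
            norm.append("(")
        elif ch in _LF_CLOSE:
            norm.append(")")
        else:
            norm.append(ch)
    s = "".join(norm)
    tree, pos = _lf_expr(s, 0)
    pos = _lf_skip_ws(s, pos)
    if pos != len(s):
        raise PedigreeParseError(f"unexpected {s[pos]!r}", offset=pos)
    return tree


def _lf_skip_ws(s: str, i: int) -> int:
    while i < len(s) and s[i].isspace():
        i += 1
    return i


def _lf_expr(s: str, i: int) -> tuple[CrossTree, int]:
    node, i = _lf_term(s, i)
    while True:
        j = _lf_skip_ws(s, i)
        if j < len(s) and s[j] == "*":
            right, i = _lf_term(s, j + 1)
            node = cross(node, right)
        else:
            return node, i


def _lf_term(s: str, i: int) -> tuple[CrossTree, int]:
    i = _lf_skip_ws(s, i)
    if i >= len(s):
        raise PedigreeParseError("empty operand", offset=i)
    if s[i] == "(":
        node, j = _lf_expr(s, i + 1)
        j = _lf_skip_ws(s, j)
        if j >= len(s) or s[j] != ")":
            raise PedigreeParseError("unbalanced bracket", offset=i)
        return node, j + 1
    if s[i] in "*)":
        raise PedigreeParseError("empty operand", offset=i)
    j = i
    while j < len(s) and s[j] not in "*()":
        j += 1
    name = s[i:j].strip()
    if not name:
        raise PedigreeParseError("empty operand", offset=i)
    return founder(name), j


# ---------------------------------------------------------------------------
# Dialect dispatch


def parse_pedigree_string(text: str, dialect: str = "auto") -> CrossTree:
    """Parse ``text`` in the named dialect (``purdy``, ``lamacraft`` or ``auto``).

    ``auto`` chooses Lamacraft–Finlay when a ``*``/``×`` operator or bracket
    is present, Purdy otherwise.  A string mixing slash separators with
    star operators is rejected: such records need manual curation.
    """
    if not text or not text.strip():
        raise PedigreeParseError("empty pedigree string", offset=0)
    if dialect == "purdy":
        return parse_purdy(text)
    if dialect == "lamacraft":
        return parse_lamacraft(text)
    if dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}")
    has_slash = "/" in text
    has_star = any(c in text for c in "*×([")
    if has_slash and has_star:
        raise PedigreeParseError(
            "mixed notation: both Purdy '/' separators and "
            "Lamacraft '*'/bracket cues present"
        )
    return parse_lamacraft(text) if has_star else parse_purdy(text)


# ---------------------------------------------------------------------------
# Serialisation and atomisation


def _order(tree: CrossTree) -> int:
    """Cross depth used to choose the Purdy separator: founders 0, a cross
    one more than its deeper side."""
    if tree.is_founder:
        return 0
    return 1 + max(_order(tree.left), _order(tree.right))  # type: ignore[arg-type]


def _sep(order: int) -> str:
    if order == 1:
        return "/"
    if order == 2:
        return "//"
    return f"/{order}/"


def serialize_purdy_tree(tree: CrossTree) -> str:
    """Serialise a cross tree to strict Purdy notation.

    The separator order at each cross equals its cross depth, so the
    top-level separator of any substring is unique and
    ``parse_purdy(serialize_purdy_tree(t))`` reproduces ``t`` exactly.
    """
    if tree.is_founder:
        return tree.name
    left = serialize_purdy_tree(tree.left)  # type: ignore[arg-type]
    right = serialize_purdy_tree(tree.right)  # type: ignore[arg-type]
    return f"{left}{_sep(_order(tree))}{right}"


def atomise(name: str, tree: CrossTree) -> list[ParentChildRecord]:
    """Decompose a cross tree into elementary parent/child records.

    The root cross is named ``name``; every interior (anonymous) cross gets
    a deterministic canonical name equal to its Purdy serialisation, which
    also merges repeated identical sub-crosses into a single line.  Records
    are emitted parents-before-children.
    """
    if not name:
        raise ValueError("line name must be non-empty")
    if tree.is_founder:
        return []
    records: list[ParentChildRecord] = []
    emitted: set[str] = set()

    def node_name(node: CrossTree, is_root: bool) -> str:
        if node.is_founder:
            return node.name
        return name if is_root else serialize_purdy_tree(node)

    def walk(node: CrossTree, is_root: bool) -> str:
        this = node_name(node, is_root)
        if node.is_founder:
            return this
        p1 = walk(node.left, False)  # type: ignore[arg-type]
        p2 = walk(node.right, False)  # type: ignore[arg-type]
        if this not in emitted:
            emitted.add(this)
            records.append(
                ParentChildRecord(this, p1, p2, cross_type=node.cross_type)
            )
        return this

    walk(tree, True)
    return records


def trees_isomorphic(a: CrossTree, b: CrossTree) -> bool:
    """Structural equality of two cross trees (names, shape; cross_type ignored)."""
    if a.is_founder != b.is_founder:
        return False
    if a.is_founder:
        return a.name == b.name
    return trees_isomorphic(a.left, b.left) and trees_isomorphic(a.right, b.right)  # type: ignore[arg-type]
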