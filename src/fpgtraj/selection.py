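"""A small atom-selection language over a Topology.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | primary
    primary  := "(" expr ")"
              | "within" NUMBER "of" primary      # needs a context snapshot
              | "name" LIST | "resname" LIST | "chain" LIST
              | "resnum" RANGES | "serial" RANGES | "element" LIST
              | "protein" | "dna" | "water" | "ion" | "other"
              | "all" | "none"

Lists are comma-separated (``resname HOH,WAT``); ranges accept ``5``,
``1-10`` and comma combinations (an empty range such as ``1-0`` selects
nothing).  Resolution is deterministic: an ascending atom-index array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .topology import Topology

_KEYWORDS = {"and", "or", "not", "within", "of", "name", "resname", "chain",
             "resnum", "serial", "element", "protein", "dna", "water", "ion",
             "other", "all", "none", "(", ")"}


@dataclass
class Selection:
    """A parsed selection expression (validated at construction)."""

    expression: str

    def __post_init__(self) -> None:
        self._ast = _Parser(self.expression).parse()

    @property
    def needs_snapshot(self) -> bool:
        return _needs_snapshot(self._ast)

    def resolve(self, topology: Topology,
                context_snapshot: np.ndarray | None = None) -> np.ndarray:
        mask = _eval(self._ast, topology, context_snapshot)
        return np.flatnonzero(mask)


def resolve_selection(topology: Topology, selection: Selection | str,
                      context_snapshot: np.ndarray | None = None) -> np.ndarray:
    """Resolve a selection (or expression string) to sorted atom indices."""
    if isinstance(selection, str):
        selection = Selection(selection)
    return selection.resolve(topology, context_snapshot)


class SelectionSyntaxError(ValueError):
    pass


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(text) and not text[j].isspace() and text[j] not in "()":
            j += 1
        tokens.append((text[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos][0].lower() if self.pos < len(self.tokens) else None

    def _next(self):
        if self.pos >= len(self.tokens):
            raise SelectionSyntaxError(
                f"unexpected end of selection {self.text!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionSyntaxError(
                f"unexpected token {tok!r} at position {at} in {self.text!r}")
        return node

    def _or(self):
        node = self._and()
        while self._peek() == "or":
            self._next()
            node = ("or", node, self._and())
        return node

    def _and(self):
        node = self._unary()
        while self._peek() == "and":
            self._next()
            node = ("and", node, self._unary())
        return node

    def _unary(self):
        if self._peek() == "not":
            self._next()
            return ("not", self._unary())
        return self._primary()

    def _primary(self):
        tok, at = self._next()
        low = tok.lower()
        if low == "(":
            node = self._or()
            closing, cat = self._next()
            if closing != ")":
                raise SelectionSyntaxError(
                    f"expected ')' at position {cat} in {self.text!r}")
            return node
        if low == "within":
            rtok, rat = self._next()
            try:
                radius = float(rtok)
            except ValueError:
                raise SelectionSyntaxError(
                    f"expected a distance after 'within' at position {rat}")
            of, oat = self._next()
            if of.lower() != "of":
                raise SelectionSyntaxError(
                    f"expected 'of' at position {oat} in {self.text!r}")
            return ("within", radius, self._unary())
        if low in ("protein", "dna", "water", "ion", "other"):
            return ("class", low)
        if low in ("all", "none"):
            return (low,)
        if low in ("name", "resname", "chain", "element"):
            val, _ = self._next_value(at)
            return (low, tuple(v for v in val.split(",") if v))
        if low in ("resnum", "serial"):
            val, vat = self._next_value(at)
            return (low, _parse_ranges(val, vat))
        raise SelectionSyntaxError(
            f"unexpected token {tok!r} at position {at} in {self.text!r}")

    def _next_value(self, at: int):
        if self.pos >= len(self.tokens):
            raise SelectionSyntaxError(
                f"keyword at position {at} needs an argument in {self.text!r}")
        val, vat = self._next()
        if val.lower() in _KEYWORDS:
            raise SelectionSyntaxError(
                f"keyword at position {at} needs an argument, got {val!r}")
        return val, vat


def _parse_ranges(text: str, at: int) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        if not part:
            continue
        # split on '-' but allow a leading minus for negative residue numbers
        body = part
        sep = body.find("-", 1)
        try:
            if sep == -1:
                v = int(body)
                out.append((v, v))
            else:
                out.append((int(body[:sep]), int(body[sep + 1:])))
        except ValueError:
            raise SelectionSyntaxError(
                f"bad range {part!r} at position {at}")
    return tuple(out)


def _needs_snapshot(node) -> bool:
    if node[0] == "within":
        return True
    return any(_needs_snapshot(c) for c in node[1:]
               if isinstance(c, tuple) and c and isinstance(c[0], str))


def _eval(node, top: Topology, snap: np.ndarray | None) -> np.ndarray:
    op = node[0]
    n = top.n_atoms
    if op == "all":
        return np.ones(n, dtype=bool)
    if op == "none":
        return np.zeros(n, dtype=bool)
    if op == "and":
        return _eval(node[1], top, snap) & _eval(node[2], top, snap)
    if op == "or":
        return _eval(node[1], top, snap) | _eval(node[2], top, snap)
    if op == "not":
        return ~_eval(node[1], top, snap)
    if op == "name":
        return np.isin(top.names, node[1])
    if op == "resname":
        vals = tuple(v.upper() for v in node[1])
        return np.isin(np.char.upper(top.res_names.astype(str)), vals)
    if op == "chain":
        return np.isin(top.chain_ids, node[1])
    if op == "element":
        return np.isin(top.elements, tuple(v.upper() for v in node[1]))
    if op == "resnum":
        mask = np.zeros(n, dtype=bool)
        for lo, hi in node[1]:
            mask |= (top.res_numbers >= lo) & (top.res_numbers <= hi)
        return mask
    if op == "serial":
        mask = np.zeros(n, dtype=bool)
        for lo, hi in node[1]:
            mask |= (top.serials >= lo) & (top.serials <= hi)
        return mask
    if op == "class":
        return top.atom_classes == node[1]
    if op == "within":
        if snap is None:
            raise ValueError("'within' selection requires a context snapshot")
        radius, sub = node[1], node[2]
        ref = _eval(sub, top, snap)
        if not ref.any():
            return np.zeros(n, dtype=bool)
        tree = cKDTree(snap[ref])
        d, _ = tree.query(snap, k=1, distance_upper_bound=radius + 1e-12)
        return np.isfinite(d) & (d <= radius)
    raise AssertionError(f"unhandled node {op}")
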