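"""KEGG module DEFINITION parsing and completeness scoring.

A module DEFINITION string encodes a reaction pathway as an expression over
KEGG Orthology (KO) identifiers:

* space — sequential steps (all required);
* comma — alternatives (any branch suffices);
* plus — an enzyme complex (all subunits required);
* minus — an optional / non-essential component (never counted against
  completeness);
* parentheses — grouping.

Operator precedence, tightest first: minus, plus, comma, space.

Completeness of a module given a genome's KO set is, in the default
"strict-steps" mode, the percentage of satisfied non-optional top-level
steps, with nested groups satisfied all-or-nothing. A "fractional" mode
(the style of annotation suites that average over nested structure) is
also available: sequences average their parts, alternatives take the best
branch, complexes average their subunits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "ModuleDefinition",
    "parse_definition",
    "module_completeness",
    "completeness_matrix",
    "filter_modules",
    "combined_pathway_completeness",
    "kos_per_mbp",
]


# ---------------------------------------------------------------------------
# expression tree


@dataclass
class Node:
    kind: str  # "ko" | "seq" | "alt" | "complex" | "optional" | "group"
    ko: str | None = None
    children: list["Node"] = field(default_factory=list)

    def leaves(self) -> set[str]:
        if self.kind == "ko":
            return {self.ko}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return out


@dataclass
class ModuleDefinition:
    """A parsed module: id, category and DEFINITION expression tree."""

    module_id: str
    category: str
    definition: str
    root: Node

    def kos(self) -> set[str]:
        return self.root.leaves()

    def to_string(self) -> str:
        return _serialize(self.root)


# ---------------------------------------------------------------------------
# parser: recursive descent, precedence minus > plus > comma > space

_TOKEN = re.compile(r"[A-Za-z0-9_.]+|[ ,+\-()]")
_IDENT = re.compile(r"[A-Za-z0-9_.]+$")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise ParseError(msg, position=self.pos)

    def peek(self) -> str | None:
        return self.text[self.pos] if self.pos < len(self.text) else None

    def take_ident(self) -> str:
        m = re.match(r"[A-Za-z0-9_.]+", self.text[self.pos:])
        if not m:
            self.error("expected a KO identifier")
        self.pos += m.end()
        return m.group(0)

    def parse(self) -> Node:
        node = self.seq()
        if self.pos != len(self.text):
            self.error(f"unexpected character {self.text[self.pos]!r}")
        return node

    def seq(self) -> Node:
        parts = [self.alt()]
        while self.peek() == " ":
            self.pos += 1
            parts.append(self.alt())
        return parts[0] if len(parts) == 1 else Node("seq", children=parts)

    def alt(self) -> Node:
        parts = [self.cpx()]
        while self.peek() == ",":
            self.pos += 1
            parts.append(self.cpx())
        return parts[0] if len(parts) == 1 else Node("alt", children=parts)

    def cpx(self) -> Node:
        parts = []
        if self.peek() == "-":  # leading minus: whole first component optional
            self.pos += 1
            parts.append(Node("optional", children=[self.prim()]))
        else:
            parts.append(self.prim())
        while self.peek() in ("+", "-"):
            op = self.text[self.pos]
            self.pos += 1
            nxt = self.prim()
            parts.append(Node("optional", children=[nxt]) if op == "-" else nxt)
        return parts[0] if len(parts) == 1 else Node("complex", children=parts)

    def prim(self) -> Node:
        ch = self.peek()
        if ch == "(":
            self.pos += 1
            inner = self.seq()
            if self.peek() != ")":
                self.error("unbalanced parentheses")
            self.pos += 1
            # explicit group node: a parenthesised sub-pathway is a single
            # all-or-nothing unit wherever it appears as a step
            return Node("group", children=[inner])
        if ch is None or ch in " ,+-)":
            self.error("dangling operator")
        return Node("ko", ko=self.take_ident())


def parse_definition(
    defn: str, module_id: str = "", category: str = "other"
) -> ModuleDefinition:
    """Parse a DEFINITION string into a :class:`ModuleDefinition`.

    Raises :class:`ParseError` (with position) on unbalanced parentheses
    or dangling operators.
    """
    defn = defn.strip()
    if not defn:
        raise ParseError("empty definition", position=0)
    root = _Parser(defn).parse()
    return ModuleDefinition(module_id=module_id, category=category, definition=defn, root=root)


def _serialize(node: Node) -> str:
    if node.kind == "ko":
        return node.ko
    if node.kind == "group":
        return f"({_serialize(node.children[0])})"
    if node.kind == "optional":
        return "-" + _serialize(node.children[0])
    if node.kind == "complex":
        out = _serialize(node.children[0])
        for c in node.children[1:]:
            if c.kind == "optional":
                out += "-" + _serialize(c.children[0])
            else:
                out += "+" + _serialize(c)
        return out
    if node.kind == "alt":
        return ",".join(_serialize(c) for c in node.children)
    if node.kind == "seq":
        return " ".join(_serialize(c) for c in node.children)
    raise AssertionError(node.kind)


# ---------------------------------------------------------------------------
# completeness


def _satisfied(node: Node, kos: set[str]) -> bool:
    if node.kind == "ko":
        return node.ko in kos
    if node.kind == "optional":
        return True
    if node.kind == "group":
        return _satisfied(node.children[0], kos)
    if node.kind == "alt":
        return any(_satisfied(c, kos) for c in node.children)
    # seq and complex: every non-optional part required
    return all(_satisfied(c, kos) for c in node.children if c.kind != "optional")


def _fractional(node: Node, kos: set[str]) -> float:
    if node.kind == "ko":
        return 1.0 if node.ko in kos else 0.0
    if node.kind == "optional":
        return 1.0
    if node.kind == "group":
        return _fractional(node.children[0], kos)
    if node.kind == "alt":
        return max(_fractional(c, kos) for c in node.children)
    required = [c for c in node.children if c.kind != "optional"]
    if not required:
        return 1.0
    return float(np.mean([_fractional(c, kos) for c in required]))


def module_completeness(
    module: ModuleDefinition, kos: set[str], mode: str = "strict-steps"
) -> float:
    """Completeness (%) of a module given a genome's KO set.

    ``strict-steps`` (default): 100 x satisfied non-optional top-level
    steps / total non-optional top-level steps, with each step — including
    parenthesised groups — satisfied all-or-nothing. ``fractional``:
    recursive averaging (sequences average, alternatives take the best
    branch). A module whose steps are all optional has undefined
    completeness, returned as NaN.
    """
    root = module.root
    steps = root.children if root.kind == "seq" else [root]
    required = [s for s in steps if s.kind != "optional"]
    if not required:
        return float("nan")
    if mode == "strict-steps":
        return 100.0 * sum(_satisfied(s, kos) for s in required) / len(required)
    if mode == "fractional":
        return 100.0 * float(np.mean([_fractional(s, kos) for s in required]))
    raise DomainError(f"unknown completeness mode {mode!r}")


def completeness_matrix(
    modules: list[ModuleDefinition],
    ko_table: pd.DataFrame,
    mode: str = "strict-steps",
) -> pd.DataFrame:
    """Genome x module completeness matrix from a boolean genome x KO table."""
    out = {}
    ko_sets = {
        gid: set(ko_table.columns[ko_table.loc[gid].astype(bool)]) for gid in ko_table.index
    }
    for m in modules:
        out[m.module_id] = [module_completeness(m, ko_sets[gid], mode=mode) for gid in ko_table.index]
    return pd.DataFrame(out, index=ko_table.index)


def filter_modules(
    completeness: pd.DataFrame,
    min_fraction_nonzero: float = 0.2,
) -> list[str]:
    """Module retention filter.

    Keeps modules for which (1) at least one genome reaches 100%
    completeness, and (2) at least ``min_fraction_nonzero`` of genomes
    have completeness > 0%. Returns retained module ids, preserving
    column order; idempotent and order-independent.
    """
    kept = []
    n = completeness.shape[0]
    for mod in completeness.columns:
        col = completeness[mod]
        if (col >= 100.0 - 1e-9).any() and (col > 0).sum() / n >= min_fraction_nonzero:
            kept.append(mod)
    return kept


def combined_pathway_completeness(
    modules: list[ModuleDefinition],
    kos: set[str],
    mode: str = "strict-steps",
    weighting: str = "module",
) -> float:
    """Completeness of a combined pathway spanning several modules.

    ``weighting="module"`` (default): unweighted mean of member-module
    completeness. ``weighting="step"``: satisfied required steps pooled
    over all members divided by the pooled step count (strict-steps mode
    only).
    """
    if not modules:
        raise DomainError("combined pathway needs at least one module")
    if weighting == "module":
        vals = [module_completeness(m, kos, mode=mode) for m in modules]
        return float(np.nanmean(vals))
    if weighting == "step":
        sat = tot = 0
        for m in modules:
            steps = m.root.children if m.root.kind == "seq" else [m.root]
            required = [s for s in steps if s.kind != "optional"]
            sat += sum(_satisfied(s, kos) for s in required)
            tot += len(required)
        if tot == 0:
            return float("nan")
        return 100.0 * sat / tot
    raise DomainError(f"unknown weighting {weighting!r}")


def kos_per_mbp(
    kos: set[str], category_map: dict[str, set[str] | list[str]], estimated_size: float
) -> dict[str, float]:
    """Distinct KOs per functional category divided by genome size in Mbp."""
    if estimated_size <= 0:
        raise DomainError("estimated_size must be positive")
    mbp = estimated_size / 1e6
    return {cat: len(kos & set(members)) / mbp for cat, members in category_map.items()}
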