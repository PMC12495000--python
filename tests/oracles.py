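"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the TAD oracle is a
literal sort-trim-mean; the SparCC oracle builds the basis-variance system
with explicit Python loops; the module-completeness oracle evaluates the
DEFINITION string by recursive text splitting, never touching the
package's parser or expression tree.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

# --------------------------------------------------------------------------- TAD


def tad_oracle(depths, central_fraction: float = 0.8) -> float:
    """Literal sort / trim floor(((1-cf)/2)*L) per side / mean.

    The per-side trim count is computed in exact rational arithmetic.
    """
    d = sorted(float(v) for v in depths)
    L = len(d)
    cf = Fraction(str(central_fraction))
    k = math.floor((1 - cf) / 2 * L)
    kept = d[k : L - k]
    return sum(kept) / len(kept)


# --------------------------------------------------------------------------- SparCC


def sparcc_oracle(
    frac: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
) -> np.ndarray:
    """Naive loop-based SparCC on one fraction matrix (species x samples)."""
    frac = np.asarray(frac, dtype=float)
    D, _ = frac.shape
    if max_exclusions is None:
        max_exclusions = D - 4
    logx = np.log(frac)
    t = np.zeros((D, D))
    for i in range(D):
        for j in range(D):
            if i != j:
                t[i, j] = np.var(logx[i] - logx[j], ddof=1)

    excluded: set[frozenset] = set()

    def solve():
        M = np.full((D, D), 1.0)
        for i in range(D):
            M[i, i] = D - 1
        rhs = np.zeros(D)
        for pair in excluded:
            i, j = sorted(pair)
            M[i, j] -= 1.0
            M[j, i] -= 1.0
            M[i, i] -= 1.0
            M[j, j] -= 1.0
        for i in range(D):
            rhs[i] = sum(
                t[i, j] for j in range(D) if j != i and frozenset((i, j)) not in excluded
            )
        w = np.linalg.solve(M, rhs)
        w = np.maximum(w, 1e-12)
        rho = np.ones((D, D))
        for i in range(D):
            for j in range(D):
                if i != j:
                    val = (w[i] + w[j] - t[i, j]) / (2.0 * math.sqrt(w[i] * w[j]))
                    rho[i, j] = min(1.0, max(-1.0, val))
        return rho

    rho = solve()
    for _ in range(max_exclusions):
        best, best_val = None, exclusion_threshold
        for i in range(D):
            for j in range(i + 1, D):
                if frozenset((i, j)) in excluded:
                    continue
                if abs(rho[i, j]) > best_val:
                    best, best_val = (i, j), abs(rho[i, j])
        if best is None:
            break
        excluded.add(frozenset(best))
        rho = solve()
    return rho


# --------------------------------------------------------------------------- KEGG module completeness


def _split_top(text: str, sep: str) -> list[str]:
    """Split on `sep` at parenthesis depth 0."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _strip_parens(text: str) -> str:
    while text.startswith("(") and text.endswith(")"):
        depth = 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0 and i < len(text) - 1:
                    return text
        text = text[1:-1]
    return text


def _split_pm(text: str) -> list[tuple[str, str]]:
    """Split a complex on top-level +/- keeping the sign of each part."""
    parts: list[tuple[str, str]] = []
    depth, cur, op = 0, [], "+"
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth == 0 and ch in "+-":
            if cur:
                parts.append((op, "".join(cur)))
            op, cur = ch, []
        else:
            cur.append(ch)
    parts.append((op, "".join(cur)))
    return parts


def _is_optional_step(step: str) -> bool:
    parts = _split_pm(step.strip())
    return all(op == "-" for op, _ in parts)


def _sat(text: str, kos: set) -> bool:
    """Is this (sub)expression fully satisfied? Pure string recursion."""
    text = _strip_parens(text.strip())
    steps = _split_top(text, " ")
    if len(steps) > 1:
        return all(_sat(s, kos) for s in steps if not _is_optional_step(s))
    alts = _split_top(text, ",")
    if len(alts) > 1:
        return any(_sat(a, kos) for a in alts)
    parts = _split_pm(text)
    if len(parts) > 1 or parts[0][0] == "-":
        required = [p for op, p in parts if op == "+"]
        return all(_sat(p, kos) for p in required)  # vacuously True if all optional
    inner = parts[0][1]
    if inner.startswith("("):
        return _sat(inner, kos)
    return inner in kos


def completeness_oracle(defn: str, kos: set) -> float:
    """Strict-steps completeness (%) by direct string evaluation."""
    steps = _split_top(defn.strip(), " ")
    required = [s for s in steps if not _is_optional_step(s)]
    if not required:
        return float("nan")
    return 100.0 * sum(_sat(s, kos) for s in required) / len(required)


# --------------------------------------------------------------------------- random DEFINITION strings


def random_definition(rng: np.random.Generator, max_depth: int = 2) -> str:
    """A random well-formed DEFINITION string exercising the grammar."""

    def ko() -> str:
        return f"K{rng.integers(0, 100):05d}"

    def atom(depth: int) -> str:
        if depth < max_depth and rng.random() < 0.3:
            return "(" + seq(depth + 1) + ")"
        return ko()

    def cpx(depth: int) -> str:
        n = int(rng.integers(1, 4))
        out = atom(depth)
        for _ in range(n - 1):
            out += ("-" if rng.random() < 0.25 else "+") + atom(depth)
        return out

    def alt(depth: int) -> str:
        n = int(rng.integers(1, 3))
        return ",".join(cpx(depth) for _ in range(n + (0 if rng.random() < 0.6 else 1)))

    def seq(depth: int) -> str:
        n = int(rng.integers(1, 5))
        return " ".join(alt(depth) for _ in range(n))

    return seq(0)
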