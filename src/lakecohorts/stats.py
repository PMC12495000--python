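"""Cross-cutting statistics: OLS/Pearson fits with residuals,
Kruskal–Wallis group comparison with Benjamini–Hochberg correction,
z-scores, and the coefficient of variation.

All standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "linear_fit",
    "kruskal_wallis_bh",
    "zscore",
    "bh_adjust",
    "coefficient_of_variation",
]


@dataclass
class RegressionResult:
    """Simple OLS fit: slope/intercept, Pearson r, and residuals."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    residuals: np.ndarray
    degenerate_y: bool = False  # constant response: r undefined

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class GroupTestResult:
    """Kruskal–Wallis H with BH-corrected pairwise rank-sum comparisons."""

    groups: list
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, raw_p, adjusted_p
    letters: dict  # compact letter display


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and residuals.

    Requires >= 3 finite pairs and non-constant x. A constant y gives
    slope 0 and an undefined (NaN) r, flagged via ``degenerate_y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DomainError("linear fit needs at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise DomainError("x has zero variance; fit undefined")
    if np.ptp(y) == 0:
        res = RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            pearson_r=float("nan"),
            r_squared=float("nan"),
            residuals=y - y[0],
            degenerate_y=True,
        )
        return res
    fit = sps.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        residuals=residuals,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def zscore(x) -> np.ndarray:
    """Standardise to mean 0, sample sd 1: ``(x - mean(x)) / sd(x)``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("z-score needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("zero standard deviation; z-score undefined")
    return (x - x.mean()) / sd


def coefficient_of_variation(x) -> float:
    """CV (%) = sample sd / mean * 100."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise DomainError("zero mean; CV undefined")
    return float(x.std(ddof=1) / mean * 100.0)


def _letter_display(groups: list, differs) -> dict:
    """Greedy compact-letter display: groups not significantly different
    share at least one letter."""
    letters: dict = {g: set() for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    next_letter = 0
    for g in groups:
        placed = False
        for letter in sorted({l for s in letters.values() for l in s}):
            holders = [h for h in groups if letter in letters[h]]
            if holders and all(not differs(g, h) for h in holders):
                letters[g].add(letter)
                placed = True
        if not placed:
            letters[g].add(alphabet[next_letter % len(alphabet)])
            next_letter += 1
    # ensure every group has a letter distinct from all significantly
    # different groups (greedy pass above can leave clashes only when a
    # group shares no letter; add fresh letters as needed)
    for g in groups:
        if not letters[g]:
            letters[g].add(alphabet[next_letter % len(alphabet)])
            next_letter += 1
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def kruskal_wallis_bh(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """Kruskal–Wallis across groups with BH-corrected pairwise rank-sum
    tests and a compact letter display.

    ``values`` and ``groups`` are parallel sequences. The omnibus H uses
    tie correction (scipy). Pairwise comparisons are two-sided
    Mann–Whitney rank-sum tests; the BH adjustment runs over the pairwise
    family, and two groups get different letters when their adjusted
    p < ``alpha``. Identical samples in all groups give H = 0 and shared
    letters. A single group yields no test and the identity letter.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist(), key=str)
    samples = {g: values[groups == g] for g in labels}
    if any(s.size == 0 for s in samples.values()):
        raise DomainError("every group needs at least one observation")
    if len(labels) < 2:
        return GroupTestResult(
            groups=labels,
            h_statistic=0.0,
            p_value=1.0,
            pairwise=pd.DataFrame(columns=["group_a", "group_b", "raw_p", "adjusted_p"]),
            letters={labels[0]: "a"},
        )
    if all(np.array_equal(samples[g], samples[labels[0]]) for g in labels):
        h, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h, p = sps.kruskal(*[samples[g] for g in labels])
    rows = []
    for a, b in itertools.combinations(labels, 2):
        if np.array_equal(samples[a], samples[b]):
            raw = 1.0
        else:
            raw = float(sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue)
        rows.append({"group_a": a, "group_b": b, "raw_p": raw})
    pairwise = pd.DataFrame(rows)
    pairwise["adjusted_p"] = bh_adjust(pairwise["raw_p"].to_numpy())
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.adjusted_p < alpha
    }
    letters = _letter_display(labels, lambda g, h2: frozenset((g, h2)) in sig)
    return GroupTestResult(
        groups=labels, h_statistic=float(h), p_value=float(p), pairwise=pairwise, letters=letters
    )
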