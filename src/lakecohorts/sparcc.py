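"""SparCC compositional correlation with bootstrap p-values.

Relative abundances are compositional: closure to a constant sum induces
spurious negative correlation between components. SparCC sidesteps this by
working with log-ratio variances ``t_ij = Var(log(x_i / x_j))``, which are
invariant to the closure. Writing ``t_ij = w_i + w_j - 2 rho_ij
sqrt(w_i w_j)`` in terms of unobserved basis variances ``w_i`` and basis
correlations ``rho_ij``, and assuming the correlation network is sparse
(so correlation terms approximately cancel when summed over partners), the
basis variances solve the linear system

    M w = t_row_sums,   M = 1 1^T + (D - 2) I,

after which ``rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))``. Strongly
correlated pairs violate the sparsity assumption, so the estimator
iteratively excludes the most correlated pair above an exclusion threshold
from the system and re-solves.

Significance is assessed by a permutation bootstrap: every species' vector
is shuffled across samples independently, the estimator is re-run, and the
p-value of a pair is the raw proportion of null correlations at least as
large as the observed one (one-sided, upper tail — only positive
co-occurrences are retained downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, InputError

__all__ = [
    "FilteredMatrix",
    "SparccResult",
    "prefilter",
    "sparcc_correlation",
    "bootstrap_pvalues",
    "build_edges",
]


@dataclass
class FilteredMatrix:
    """Abundance matrix surviving the prevalence/abundance prefilter."""

    abundance: pd.DataFrame
    dropped: pd.DataFrame  # species -> reason bookkeeping


@dataclass
class SparccResult:
    """Correlation and bootstrap p-value matrices with run parameters."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame | None
    n_boot: int
    n_inner_iterations: int
    exclusion_threshold: float
    seed: int | None


def prefilter(
    abundance: pd.DataFrame,
    min_samples: int = 3,
    min_overall_abundance: float = 1e-4,
    overall: str = "mean",
) -> FilteredMatrix:
    """Drop rare species before network inference.

    Retains species detected (abundance > 0) in at least ``min_samples``
    samples AND whose overall relative abundance exceeds
    ``min_overall_abundance``. "Overall" defaults to the mean across all
    samples; ``overall`` may also be ``"max"`` or ``"sum"``.
    """
    det = (abundance > 0).sum(axis=1)
    if overall == "mean":
        level = abundance.mean(axis=1)
    elif overall == "max":
        level = abundance.max(axis=1)
    elif overall == "sum":
        level = abundance.sum(axis=1)
    else:
        raise ConfigurationError(f"unknown overall-abundance mode {overall!r}")
    keep = (det >= min_samples) & (level > min_overall_abundance)
    dropped = pd.DataFrame(
        {
            "n_detected": det[~keep],
            "overall_abundance": level[~keep],
            "failed_min_samples": (det < min_samples)[~keep],
            "failed_abundance_floor": (level <= min_overall_abundance)[~keep],
        }
    )
    if keep.sum() == 0:
        warnings.warn("prefilter removed every species; downstream network will be empty")
    return FilteredMatrix(abundance=abundance.loc[keep], dropped=dropped)


def _replace_zeros(frac: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest positive value, then re-close columns."""
    if (frac > 0).any():
        tiny = frac[frac > 0].min() / 2.0
    else:
        raise DomainError("abundance matrix is identically zero")
    out = np.where(frac > 0, frac, tiny)
    return out / out.sum(axis=0, keepdims=True)


def _sparcc_single(
    frac: np.ndarray, exclusion_threshold: float, max_exclusions: int
) -> np.ndarray:
    """One SparCC pass on a fraction matrix (species x samples)."""
    d = frac.shape[0]
    logx = np.log(frac)
    cov = np.cov(logx, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov  # log-ratio variance matrix
    np.fill_diagonal(t, 0.0)

    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    rhs = t.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)

    def solve() -> np.ndarray:
        w = np.linalg.solve(m, rhs)
        if (w <= 0).any():
            warnings.warn("non-positive basis variance; clipping to a small positive value")
            w = np.maximum(w, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.clip(rho, -1.0, 1.0, out=rho)
        np.fill_diagonal(rho, 1.0)
        return rho

    rho = solve()
    for _ in range(max_exclusions):
        cand = np.abs(rho)
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        # remove the pair's log-ratio variance from the basis system
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        rhs[i] -= t[i, j]
        rhs[j] -= t[i, j]
        rho = solve()
    return rho


def sparcc_correlation(
    matrix: pd.DataFrame,
    n_inner_iterations: int = 50,
    exclusion_threshold: float = 0.1,
    max_exclusions: int | None = None,
    seed: int | None = None,
    counts: bool = False,
    aggregate: str = "median",
    fraction_draws: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """SparCC correlation matrix of a species x sample abundance table.

    With relative-abundance input (the default) the per-sample fractions
    are fixed — columns are renormalised once and a single deterministic
    pass is made. With ``counts=True`` (integer count input), each of the
    ``n_inner_iterations`` inner iterations draws per-sample fractions from
    the Dirichlet posterior with a +1 pseudo-count, and the returned matrix
    is the ``aggregate`` ("median" or "mean") over iterations.
    ``fraction_draws`` supplies pre-drawn fraction matrices directly
    (bypassing both modes), which lets an external oracle share identical
    draws.
    """
    d, n = matrix.shape
    if d < 4:
        raise InputError("SparCC needs at least 4 species (basis system under-determined)")
    if n < 3:
        raise InputError("SparCC needs at least 3 samples")
    if max_exclusions is None:
        max_exclusions = d - 4
    if aggregate not in ("median", "mean"):
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise DomainError("abundances must be non-negative")

    if fraction_draws is not None:
        draws = [np.asarray(f, dtype=float) for f in fraction_draws]
    elif counts:
        rng = np.random.default_rng(seed)
        draws = [
            np.apply_along_axis(lambda col: rng.dirichlet(col + 1.0), 0, x)
            for _ in range(n_inner_iterations)
        ]
    else:
        draws = [_replace_zeros(x / x.sum(axis=0, keepdims=True))]

    rhos = np.stack(
        [_sparcc_single(f, exclusion_threshold, max_exclusions) for f in draws]
    )
    rho = np.median(rhos, axis=0) if aggregate == "median" else rhos.mean(axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.index, columns=matrix.index)


def bootstrap_pvalues(
    matrix: pd.DataFrame,
    observed_rho: pd.DataFrame,
    n_boot: int = 500,
    seed: int | None = None,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """One-sided permutation p-values for SparCC correlations.

    Each bootstrap permutes every species' abundances across samples
    independently (destroying all between-species association while
    keeping marginals), re-runs the estimator, and counts null
    correlations at least as large as the observed one. The p-value is
    the raw proportion over ``n_boot`` bootstraps, so a correlation above
    every null draw gets p = 0. Child seeds are derived per bootstrap
    from the root seed, making results independent of execution order.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be at least 1")
    x = matrix.to_numpy(dtype=float)
    obs = observed_rho.to_numpy(dtype=float)
    d, n = x.shape
    count_ge = np.zeros((d, d))
    for b in range(n_boot):
        rng = np.random.default_rng([0 if seed is None else seed, b])
        perm = np.empty_like(x)
        for i in range(d):
            perm[i] = x[i, rng.permutation(n)]
        null_rho = sparcc_correlation(
            pd.DataFrame(perm, index=matrix.index, columns=matrix.columns),
            seed=None,
            **sparcc_kwargs,
        ).to_numpy()
        count_ge += null_rho >= obs
    p = count_ge / n_boot
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=matrix.index, columns=matrix.index)


def build_edges(
    rho: pd.DataFrame,
    pvalues: pd.DataFrame,
    rho_min: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filtered positive co-occurrence edge list.

    Keeps pairs (i < j) with ``rho > rho_min`` and ``p < alpha`` (both
    strict); negative correlations are never kept. Returns a DataFrame
    with columns ``source, target, rho, p`` sorted by (source, target).
    """
    if list(rho.index) != list(pvalues.index) or list(rho.columns) != list(pvalues.columns):
        raise InputError("rho and p-value matrices are not aligned")
    species = list(rho.index)
    r = rho.to_numpy()
    p = pvalues.to_numpy()
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            if r[i, j] > rho_min and p[i, j] < alpha:
                rows.append((species[i], species[j], r[i, j], p[i, j]))
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p"]).sort_values(
        ["source", "target"], ignore_index=True
    )
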