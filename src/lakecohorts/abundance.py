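"""Relative abundance from depth profiles: TAD, genome equivalents,
detection and prevalence.

The abundance of a genome in a metagenome is estimated as its truncated
average depth (TAD) divided by the sample's genome equivalents. TAD with a
central fraction of 0.8 (TAD80) is the mean positional depth after
discarding the highest 10% and lowest 10% of positions, which removes
conserved-region pile-ups and mobile-element spikes. Genome equivalents —
total sequenced bp divided by the community's average genome size (AGS) —
convert depth into the expected coverage of a "typical" genome, so
TAD / GE behaves as a relative abundance.

AGS itself is estimated from universal single-copy marker-gene hit counts:
the expected number of hits per marker is inversely proportional to AGS,
so ``AGS_m = c_m * total_bp / hits_m`` per marker m with a known
calibration constant ``c_m``, aggregated as the median across markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bedgraph import read_bedgraph
from .errors import DomainError, EstimationError

__all__ = [
    "tad",
    "estimate_avg_genome_size",
    "genome_equivalents",
    "relative_abundance",
    "prevalence_and_average",
    "AbundanceMatrix",
    "abundance_from_run",
]


def tad(depths, central_fraction: float = 0.8) -> float:
    """Truncated average depth of a positional depth vector.

    Sorts positional depths, drops ``floor(((1 - central_fraction) / 2) * L)``
    entries from each end, and returns the arithmetic mean of the rest.
    Zero-depth positions are part of the distribution. With
    ``central_fraction=1`` this is the plain mean.
    """
    d = np.asarray(depths, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise DomainError("depth vector must be non-empty and 1-D")
    if not (0 < central_fraction <= 1):
        raise DomainError("central_fraction must be in (0, 1]")
    # epsilon guards the floor against float error, e.g. (1-0.8)/2*10 = 0.999...
    k = math.floor((1.0 - central_fraction) / 2.0 * d.size + 1e-9)
    d = np.sort(d)
    return float(d[k : d.size - k].mean())


def estimate_avg_genome_size(
    total_bp: float, marker_hits: dict[str, int], calibration: dict[str, float]
) -> float:
    """Median over markers of ``c_m * total_bp / hits_m`` (bp).

    Markers with zero hits are skipped; all-zero hits raise
    :class:`EstimationError`.
    """
    if total_bp <= 0:
        raise DomainError("total_bp must be positive")
    estimates = [
        calibration[m] * total_bp / h for m, h in marker_hits.items() if h > 0 and m in calibration
    ]
    if not estimates:
        raise EstimationError("no marker family with non-zero hits")
    return float(np.median(estimates))


def genome_equivalents(total_bp: float, avg_genome_size: float) -> float:
    """Total sequenced bp divided by the community's average genome size."""
    if total_bp <= 0 or avg_genome_size <= 0:
        raise DomainError("total_bp and avg_genome_size must be positive")
    return total_bp / avg_genome_size


def relative_abundance(tad80: float, ge: float) -> float:
    """TAD divided by genome equivalents."""
    if ge <= 0:
        raise DomainError("genome equivalents must be positive")
    if tad80 < 0:
        raise DomainError("TAD must be non-negative")
    return tad80 / ge


@dataclass
class AbundanceMatrix:
    """Species x sample relative abundances with detection bookkeeping.

    ``abundance`` rows are species, columns samples. ``detection`` is the
    boolean abundance > 0 mask (the default detection rule, TAD80 > 0).
    """

    abundance: pd.DataFrame
    detection: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.abundance < 0).any().any():
            raise DomainError("abundances must be non-negative")
        self.detection = self.abundance > 0

    @property
    def species(self) -> pd.Index:
        return self.abundance.index

    @property
    def samples(self) -> pd.Index:
        return self.abundance.columns


def prevalence_and_average(
    matrix: AbundanceMatrix, include_zeros: bool = False
) -> pd.DataFrame:
    """Per-species prevalence (%) and average relative abundance (%).

    Prevalence is 100 x (samples detected) / (total samples). The average
    relative abundance is taken over detected samples only by default;
    ``include_zeros=True`` averages over all samples instead. Species
    detected nowhere get average 0 with ``never_detected=True``.
    """
    ab = matrix.abundance
    if ab.shape[1] == 0:
        raise DomainError("abundance matrix has zero samples")
    det = matrix.detection
    n_det = det.sum(axis=1)
    prevalence = 100.0 * n_det / ab.shape[1]
    if include_zeros:
        avg = ab.mean(axis=1) * 100.0
    else:
        avg = (ab.where(det).sum(axis=1) / n_det.where(n_det > 0)) * 100.0
    never = n_det == 0
    avg = avg.where(~never, 0.0)
    return pd.DataFrame(
        {
            "prevalence_pct": prevalence,
            "avg_relative_abundance_pct": avg,
            "never_detected": never,
        }
    )


def abundance_from_run(
    run_dir: str | Path,
    central_fraction: float = 0.8,
    window: int = 100,
    calibration: dict[str, float] | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Compute the abundance matrix from a run directory of BedGraph
    profiles plus a ``samples.tsv`` stats table.

    Expects ``<run_dir>/bedgraph/<sample>.bedgraph`` and
    ``<run_dir>/samples.tsv`` with columns ``total_reads``, ``total_bp``
    and ``hits_<marker>`` per marker family. Returns the abundance matrix
    and a per-sample table of estimated AGS and genome equivalents.
    """
    from .config import DEFAULT_MARKER_CALIBRATION

    if calibration is None:
        calibration = DEFAULT_MARKER_CALIBRATION
    run_dir = Path(run_dir)
    stats = pd.read_csv(run_dir / "samples.tsv", sep="\t", index_col=0)
    columns = {}
    sample_rows = []
    for sample in stats.index:
        profiles = read_bedgraph(run_dir / "bedgraph" / f"{sample}.bedgraph", window=window)
        hits = {
            col[len("hits_"):]: float(stats.loc[sample, col])
            for col in stats.columns
            if col.startswith("hits_")
        }
        total_bp = float(stats.loc[sample, "total_bp"])
        ags = estimate_avg_genome_size(total_bp, hits, calibration)
        ge = genome_equivalents(total_bp, ags)
        columns[sample] = {
            genome: relative_abundance(tad(depths, central_fraction), ge)
            for genome, depths in profiles.items()
        }
        sample_rows.append({"sample": sample, "est_avg_genome_size_bp": ags, "genome_equivalents": ge})
    ab = pd.DataFrame(columns).sort_index()
    sample_stats = pd.DataFrame(sample_rows).set_index("sample")
    return AbundanceMatrix(abundance=ab), sample_stats
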