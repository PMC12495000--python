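"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

#: Distribution spec for one environmental covariate: ("normal", mean, sd)
#: or ("uniform", low, high), sampled independently per metagenome sample.
EnvSpec = tuple[str, float, float]

DEFAULT_ENV_PARAMS: dict[str, EnvSpec] = {
    # absolute latitude of the sampling site, degrees
    "abs_latitude": ("uniform", 0.0, 70.0),
    # surface water temperature, deg C
    "temperature": ("normal", 12.0, 6.0),
    # dissolved oxygen, mg/L; drives the oxygen-coupled cohort
    "oxygen": ("uniform", 0.0, 15.0),
}

#: Marker calibration constants c_m with AGS = c_m * total_bp / hits_m.
DEFAULT_MARKER_CALIBRATION: dict[str, float] = {
    "marker_%02d" % i: c
    for i, c in enumerate([600.0, 800.0, 1000.0, 1200.0, 1500.0, 700.0, 900.0, 1100.0, 1300.0, 1000.0], start=1)
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic freshwater community.

    The defaults describe a desk-scale community with four planted
    co-occurrence cohorts of 25 species each on a background of 120
    independent species, profiled across 200 metagenome samples — large
    enough for the co-occurrence machinery to resolve the planted structure,
    small enough to simulate in seconds.

    Parameters
    ----------
    n_species
        Total number of species (cohort members plus background).
    n_samples
        Number of metagenome samples.
    cohort_sizes
        Members per planted cohort; must sum to at most ``n_species``.
    noise_sd
        Log-scale standard deviation of the species-level noise added on
        top of the shared cohort factor.
    loading
        Multiplier of the shared log cohort factor in each member's
        log-abundance.
    factor_sd
        Log-scale standard deviation of the latent cohort factor itself.
    env_params
        Per-sample environmental covariates and their sampling
        distributions.
    oxygen_coupled_cohort
        Index of the cohort whose latent factor responds (logistically) to
        the oxygen covariate; ``None`` disables environmental coupling.
    coverage_target
        Mean sequencing depth (x) across species; sets per-sample genome
        equivalents to ``coverage_target * n_species``.
    genome_length_range
        True genome length range in bp (log-uniform draw).
    completeness_range, contamination_range
        Uniform draw ranges for assembly quality.
    window
        Depth-profile resolution in bp; positional depth is simulated per
        window, not per base.
    read_length
        Simulated read length in bp, used to convert total bp to reads.
    ko_slope
        Logistic slope (per Mbp of true genome size) of per-KO carriage
        probability; positive values couple biosynthetic completeness to
        genome size.
    ko_intercept
        Logistic intercept of per-KO carriage at the mid-range genome size.
    """

    n_species: int = 220
    n_samples: int = 200
    cohort_sizes: tuple[int, ...] = (25, 25, 25, 25)
    noise_sd: float = 0.5
    loading: float = 1.0
    factor_sd: float = 1.0
    env_params: dict[str, EnvSpec] = field(default_factory=lambda: dict(DEFAULT_ENV_PARAMS))
    oxygen_coupled_cohort: int | None = 0
    coverage_target: float = 10.0
    genome_length_range: tuple[float, float] = (1_000_000.0, 5_000_000.0)
    completeness_range: tuple[float, float] = (0.5, 1.0)
    contamination_range: tuple[float, float] = (0.0, 0.05)
    window: int = 100
    read_length: int = 150
    ko_slope: float = 1.5
    ko_intercept: float = 0.0
    marker_calibration: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_CALIBRATION))
    seed: int = 0

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    def validate(self) -> "SimulationConfig":
        if self.n_species < 1 or self.n_samples < 1:
            raise ConfigurationError("n_species and n_samples must be positive")
        if any(s < 1 for s in self.cohort_sizes):
            raise ConfigurationError("cohort sizes must be positive")
        if sum(self.cohort_sizes) > self.n_species:
            raise ConfigurationError(
                f"sum(cohort_sizes)={sum(self.cohort_sizes)} exceeds n_species={self.n_species}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.coverage_target <= 0:
            raise ConfigurationError("coverage_target must be positive")
        lo, hi = self.genome_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("genome_length_range must be a non-empty positive range")
        clo, chi = self.completeness_range
        if not (0 < clo <= chi <= 1):
            raise ConfigurationError("completeness_range must lie in (0, 1]")
        klo, khi = self.contamination_range
        if not (0 <= klo <= khi < 1):
            raise ConfigurationError("contamination_range must lie in [0, 1)")
        if self.window < 1:
            raise ConfigurationError("window must be at least 1 bp")
        if self.oxygen_coupled_cohort is not None and not (
            0 <= self.oxygen_coupled_cohort < self.n_cohorts
        ):
            raise ConfigurationError("oxygen_coupled_cohort out of range")
        if self.oxygen_coupled_cohort is not None and "oxygen" not in self.env_params:
            raise ConfigurationError("oxygen coupling requested but no 'oxygen' covariate configured")
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        raw["cohort_sizes"] = tuple(raw["cohort_sizes"])
        raw["genome_length_range"] = tuple(raw["genome_length_range"])
        raw["completeness_range"] = tuple(raw["completeness_range"])
        raw["contamination_range"] = tuple(raw["contamination_range"])
        raw["env_params"] = {k: tuple(v) for k, v in raw["env_params"].items()}
        return cls(**raw).validate()


@dataclass
class GroundTruth:
    """Known quantities of a simulated community, for scoring recovery.

    Attributes
    ----------
    true_abundance
        species x sample relative abundances; every column sums to 1.
    cohort_labels
        Per-species planted label: ``"cohort_<i>"`` or ``"background"``.
    true_genome_sizes
        Per-species true genome length in bp.
    true_avg_genome_size
        Per-sample abundance-weighted mean genome size in bp.
    module_completeness_true
        genome x module completeness (%) under the simulated KO repertoires;
        filled by the KO-table stage.
    """

    true_abundance: pd.DataFrame
    cohort_labels: pd.Series
    true_genome_sizes: pd.Series
    true_avg_genome_size: pd.Series | None = None
    module_completeness_true: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.true_abundance.to_csv(outdir / "true_abundance.tsv", sep="\t")
        self.cohort_labels.rename("cohort").to_csv(outdir / "cohort_labels.tsv", sep="\t")
        self.true_genome_sizes.rename("true_size_bp").to_csv(outdir / "true_genome_sizes.tsv", sep="\t")
        if self.true_avg_genome_size is not None:
            self.true_avg_genome_size.rename("true_avg_genome_size_bp").to_csv(
                outdir / "true_avg_genome_size.tsv", sep="\t"
            )
        if self.module_completeness_true is not None:
            self.module_completeness_true.to_csv(outdir / "module_completeness_true.tsv", sep="\t")

    @classmethod
    def read(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        kwargs = {}
        ags = outdir / "true_avg_genome_size.tsv"
        if ags.exists():
            kwargs["true_avg_genome_size"] = pd.read_csv(ags, sep="\t", index_col=0)[
                "true_avg_genome_size_bp"
            ]
        mc = outdir / "module_completeness_true.tsv"
        if mc.exists():
            kwargs["module_completeness_true"] = pd.read_csv(mc, sep="\t", index_col=0)
        return cls(
            true_abundance=pd.read_csv(outdir / "true_abundance.tsv", sep="\t", index_col=0),
            cohort_labels=pd.read_csv(outdir / "cohort_labels.tsv", sep="\t", index_col=0)["cohort"],
            true_genome_sizes=pd.read_csv(outdir / "true_genome_sizes.tsv", sep="\t", index_col=0)[
                "true_size_bp"
            ],
            **kwargs,
        )
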