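"""Synthetic freshwater community generator with exported ground truth.

The generator produces, in order: a genome catalog (sizes, quality,
taxonomy), cohort-structured compositional abundances driven by latent
log-normal factors (one of which can respond to an environmental covariate),
Poisson positional depth profiles written as BedGraph, marker-gene hit
counts for average-genome-size estimation, and size-coupled KO repertoires.
Every stage also returns the corresponding ground truth so downstream
recovery can be scored exactly.

The statistical picture the simulation emulates: a community where groups
of species ("cohorts") co-vary across samples because they share an
ecological driver, sitting on a background of independently fluctuating
low-abundance species; sequencing depth of each genome is proportional to
its relative abundance times the sample's genome equivalents; and larger
genomes carry more biosynthetic genes, so module completeness rises with
genome size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .bedgraph import write_bedgraph
from .catalog import GenomeRecord
from .config import GroundTruth, SimulationConfig
from .errors import ConfigurationError
from .metabolism import ModuleDefinition, module_completeness, parse_definition

__all__ = [
    "simulate_catalog",
    "simulate_abundances",
    "simulate_env_params",
    "simulate_depth_profiles",
    "simulate_ko_table",
    "simulate_ani_table",
    "synthetic_modules",
    "simulate_run",
]

# Logistic steepness of the oxygen response of the coupled cohort's latent
# factor, and the rescaling that keeps its log-sd comparable to factor_sd.
_OXY_STEEPNESS = 1.7
_OXY_SCALE = 1.8


def _species_ids(n: int) -> list[str]:
    return [f"sp_{i:04d}" for i in range(n)]


def simulate_catalog(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw a genome catalog with known true genome lengths.

    True lengths are log-uniform over ``genome_length_range``; completeness
    and contamination are uniform over their ranges; the assembly size is
    exactly ``true_length * completeness``, so the size estimator
    (assembly size / completeness) recovers the true length exactly.
    Genomes are organised into genera of ~8 species so genus-level
    statistics (which require >= 5 members) are exercised.

    Returns ``(catalog, true_sizes)`` where ``catalog`` is a list of
    :class:`GenomeRecord` and ``true_sizes`` a pandas Series in bp.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_species
    ids = _species_ids(n)
    lo, hi = config.genome_length_range
    true_len = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    true_len = np.round(true_len)
    comp = rng.uniform(*config.completeness_range, size=n)
    cont = rng.uniform(*config.contamination_range, size=n)
    derivation = rng.choice(["MAG", "SAG", "isolate"], size=n, p=[0.8, 0.1, 0.1])
    environment = rng.choice(["freshwater", "non-freshwater"], size=n, p=[0.85, 0.15])
    genus_of = np.arange(n) // 8  # contiguous blocks => every full genus has 8 members
    catalog = []
    for i in range(n):
        g = genus_of[i]
        taxonomy = (
            f"d__Bacteria;p__Phylum{g // 4:03d};c__Class{g // 4:03d};"
            f"o__Order{g // 2:03d};f__Family{g:03d};g__Genus{g:03d};s__Species{i:04d}"
        )
        catalog.append(
            GenomeRecord(
                id=ids[i],
                assembly_size=float(true_len[i]) * comp[i],
                completeness=float(comp[i]),
                contamination=float(cont[i]),
                taxonomy=taxonomy,
                derivation=str(derivation[i]),
                environment=str(environment[i]),
            )
        )
    true_sizes = pd.Series(true_len, index=ids, name="true_size_bp")
    return catalog, true_sizes


def simulate_env_params(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample per-metagenome environmental covariates (samples x parameters)."""
    samples = [f"s_{j:04d}" for j in range(config.n_samples)]
    cols = {}
    for name, (kind, a, b) in config.env_params.items():
        if kind == "normal":
            cols[name] = rng.normal(a, b, size=config.n_samples)
        elif kind == "uniform":
            cols[name] = rng.uniform(a, b, size=config.n_samples)
        else:
            raise ConfigurationError(f"unknown distribution {kind!r} for covariate {name!r}")
    return pd.DataFrame(cols, index=samples)


def simulate_abundances(
    catalog: list[GenomeRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    env: pd.DataFrame | None = None,
):
    """Draw cohort-structured compositional abundances.

    Per cohort c and sample s a latent log factor ``log f_cs`` is drawn
    N(0, factor_sd^2); the oxygen-coupled cohort instead takes a monotone
    logistic response of the (standardised) oxygen covariate. Member
    log-abundance is ``mu_g + loading * log f_cs + N(0, noise_sd^2)``;
    background species get independent noise of matched total variance.
    Columns are closed to sum to one.

    Returns ``(abundance, cohort_labels, env)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if env is None:
        env = simulate_env_params(config, rng)
    n, m = config.n_species, config.n_samples
    ids = [g.id for g in catalog]
    samples = list(env.index)

    labels = np.array(["background"] * n, dtype=object)
    pos = 0
    for c, size in enumerate(config.cohort_sizes):
        labels[pos : pos + size] = f"cohort_{c + 1}"
        pos += size

    log_factors = rng.normal(0.0, config.factor_sd, size=(config.n_cohorts, m))
    if config.oxygen_coupled_cohort is not None:
        oxy = env["oxygen"].to_numpy(dtype=float)
        z = (oxy - oxy.mean()) / oxy.std()
        log_factors[config.oxygen_coupled_cohort] = (
            config.factor_sd * _OXY_SCALE * (expit(_OXY_STEEPNESS * z) - 0.5)
        )

    # species-level baseline spread gives a realistic long-tailed
    # rank-abundance curve (most species far below the mean share)
    mu = rng.normal(0.0, 1.0, size=n)
    total_sd = np.hypot(config.loading * config.factor_sd, config.noise_sd)
    log_a = np.empty((n, m))
    pos = 0
    for c, size in enumerate(config.cohort_sizes):
        noise = rng.normal(0.0, config.noise_sd, size=(size, m))
        log_a[pos : pos + size] = (
            mu[pos : pos + size, None] + config.loading * log_factors[c][None, :] + noise
        )
        pos += size
    n_bg = n - pos
    if n_bg:
        log_a[pos:] = mu[pos:, None] + rng.normal(0.0, total_sd, size=(n_bg, m))

    a = np.exp(log_a)
    a /= a.sum(axis=0, keepdims=True)
    abundance = pd.DataFrame(a, index=ids, columns=samples)
    cohort_labels = pd.Series(labels, index=ids, name="cohort")
    return abundance, cohort_labels, env


def simulate_depth_profiles(
    true_abundance: pd.DataFrame,
    true_sizes: pd.Series,
    config: SimulationConfig,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
):
    """Write per-sample BedGraph depth profiles and a sample-stats table.

    Per-sample genome equivalents are fixed at
    ``coverage_target * n_species`` so the mean expected coverage across
    species is ``coverage_target``. Expected coverage of genome g in sample
    s is ``abundance[g, s] * GE_s``; positional depth per window is Poisson
    with that mean (or exactly the mean when ``noiseless``). Marker-gene
    hits are Binomial(total_reads, c_m * read_length / AGS_true) so that
    ``c_m * total_bp / hits`` estimates the true average genome size.

    Returns the sample-stats DataFrame (also written to
    ``samples.tsv``); ground-truth AGS per sample is in column
    ``true_avg_genome_size_bp``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    outdir = Path(outdir)
    (outdir / "bedgraph").mkdir(parents=True, exist_ok=True)
    ge = config.coverage_target * config.n_species
    sizes = true_sizes.reindex(true_abundance.index).to_numpy(dtype=float)
    n_windows = np.maximum(1, (sizes // config.window).astype(int))
    rows = []
    for sample in true_abundance.columns:
        ra = true_abundance[sample].to_numpy(dtype=float)
        ags_true = float(ra @ sizes)  # abundance-weighted mean genome size
        # round to whole reads first so total_bp is an exact multiple of the
        # read length; the realised genome equivalents then reproduce
        # total_bp / AGS exactly
        total_reads = int(round(ge * ags_true / config.read_length))
        total_bp = float(total_reads * config.read_length)
        ge_actual = total_bp / ags_true
        lam = ra * ge_actual
        profiles = {}
        for g, genome in enumerate(true_abundance.index):
            if lam[g] == 0:
                profiles[genome] = np.zeros(n_windows[g])
            elif noiseless:
                profiles[genome] = np.full(n_windows[g], lam[g])
            else:
                profiles[genome] = rng.poisson(lam[g], size=n_windows[g])
        write_bedgraph(outdir / "bedgraph" / f"{sample}.bedgraph", profiles, config.window)
        row = {
            "sample": sample,
            "total_reads": total_reads,
            "total_bp": total_bp,
            "true_avg_genome_size_bp": ags_true,
        }
        for marker, c in config.marker_calibration.items():
            p = min(1.0, c * config.read_length / ags_true)
            if noiseless:
                # exact expectation (float) so the AGS estimator inverts it
                row[f"hits_{marker}"] = total_reads * p
            else:
                row[f"hits_{marker}"] = float(rng.binomial(total_reads, p))
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("sample")
    stats.to_csv(outdir / "samples.tsv", sep="\t")
    return stats


def synthetic_modules(n_per_category: int = 8, seed: int = 42) -> list[ModuleDefinition]:
    """Generate a deterministic synthetic stand-in for a biosynthetic
    KEGG-module catalog.

    Modules span the three biosynthetic categories scored in the analysis
    (amino acid, nucleotide, vitamin) plus an "other" pool; DEFINITION
    strings exercise the full grammar (sequential steps, alternatives,
    enzyme complexes, optional subunits, nested groups).
    """
    rng = np.random.default_rng(seed)
    categories = ["amino acid", "nucleotide", "vitamin", "other"]
    ko_counter = 1
    modules = []
    for ci, cat in enumerate(categories):
        for k in range(n_per_category):
            n_steps = int(rng.integers(2, 7))
            steps = []
            for _ in range(n_steps):
                kind = rng.choice(["ko", "alt", "complex", "group"], p=[0.45, 0.25, 0.2, 0.1])
                def new_ko():
                    nonlocal ko_counter
                    ko = f"K{ko_counter:05d}"
                    ko_counter += 1
                    return ko
                if kind == "ko":
                    steps.append(new_ko())
                elif kind == "alt":
                    steps.append(",".join(new_ko() for _ in range(int(rng.integers(2, 4)))))
                elif kind == "complex":
                    parts = [new_ko() for _ in range(int(rng.integers(2, 4)))]
                    sep = "-" if rng.random() < 0.3 else "+"
                    steps.append(parts[0] + "+" + sep.join(parts[1:]))
                else:  # parenthesised two-step group
                    steps.append(f"({new_ko()} {new_ko()})")
            defn = " ".join(steps)
            modules.append(parse_definition(defn, module_id=f"SM{ci * n_per_category + k + 1:05d}", category=cat))
    return modules


def simulate_ko_table(
    catalog: list[GenomeRecord],
    modules: list[ModuleDefinition],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Draw per-genome KO repertoires whose richness grows with genome size.

    The probability that a genome carries a given KO follows a logistic
    link in its true genome size (``ko_slope`` per Mbp around the
    mid-range size), plus a per-KO prevalence offset. Module completeness
    ground truth is computed with the same evaluator the analysis stage
    uses.

    Returns ``(ko_table, module_completeness_true)``: a boolean genome x KO
    DataFrame and a genome x module completeness (%) DataFrame.
    """
    config.validate()
    if not modules:
        raise ConfigurationError("empty module list")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    kos = sorted({ko for m in modules for ko in m.kos()})
    sizes = np.array([g.estimated_size for g in catalog])
    mid = np.exp(np.mean(np.log(config.genome_length_range)))
    size_term = config.ko_slope * (sizes - mid) / 1e6
    ko_offsets = rng.normal(0.0, 0.8, size=len(kos))
    p = expit(config.ko_intercept + size_term[:, None] + ko_offsets[None, :])
    carried = rng.random(size=p.shape) < p
    ko_table = pd.DataFrame(carried, index=[g.id for g in catalog], columns=kos)
    completeness = pd.DataFrame(
        {
            m.module_id: [
                module_completeness(m, set(ko_table.columns[ko_table.loc[gid]]))
                for gid in ko_table.index
            ]
            for m in modules
        },
        index=ko_table.index,
    )
    return ko_table, completeness


def simulate_ani_table(
    catalog: list[GenomeRecord], rng: np.random.Generator, p_within: float = 0.6
) -> pd.DataFrame:
    """Simulate a sparse pairwise ANI table for dereplication tests.

    Pairs within the same genus get high ANI (93-99%, a fraction of them
    above the 95% species boundary); cross-genus pairs are omitted
    (treated as below threshold downstream).
    """
    from .catalog import parse_taxonomy

    rows = []
    by_genus: dict[str, list[str]] = {}
    for g in catalog:
        by_genus.setdefault(parse_taxonomy(g.taxonomy)["genus"], []).append(g.id)
    for members in by_genus.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_within:
                    ani = rng.uniform(95.0, 99.5)
                else:
                    ani = rng.uniform(90.0, 95.0)
                rows.append((members[i], members[j], ani))
    return pd.DataFrame(rows, columns=["id1", "id2", "ani"])


def simulate_run(
    config: SimulationConfig,
    outdir: str | Path,
    noiseless: bool = False,
    with_depth: bool = True,
    with_kos: bool = True,
) -> GroundTruth:
    """Run the full generator and persist catalog, abundances, depth
    profiles, KO tables and ground truth under ``outdir``.

    A ``manifest.json`` records the configuration and which stages ran.
    Fixed seed implies byte-identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_cat = np.random.default_rng(config.seed)
    rng_ab = np.random.default_rng(config.seed + 1)
    rng_depth = np.random.default_rng(config.seed + 2)
    rng_ko = np.random.default_rng(config.seed + 3)

    catalog, true_sizes = simulate_catalog(config, rng_cat)
    abundance, cohort_labels, env = simulate_abundances(catalog, config, rng_ab)
    truth = GroundTruth(
        true_abundance=abundance, cohort_labels=cohort_labels, true_genome_sizes=true_sizes
    )

    cat_df = pd.DataFrame(
        [
            {
                "id": g.id,
                "assembly_size": g.assembly_size,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "taxonomy": g.taxonomy,
                "derivation": g.derivation,
                "environment": g.environment,
            }
            for g in catalog
        ]
    ).set_index("id")
    cat_df.to_csv(outdir / "catalog.tsv", sep="\t")
    env.to_csv(outdir / "env_params.tsv", sep="\t")

    stages = ["catalog", "abundances"]
    if with_depth:
        stats = simulate_depth_profiles(
            abundance, true_sizes, config, outdir, rng_depth, noiseless=noiseless
        )
        truth.true_avg_genome_size = stats["true_avg_genome_size_bp"]
        stages.append("depth_profiles")
    if with_kos:
        modules = synthetic_modules()
        with open(outdir / "modules.tsv", "w") as fh:
            fh.write("module_id\tcategory\tdefinition\n")
            for m in modules:
                fh.write(f"{m.module_id}\t{m.category}\t{m.to_string()}\n")
        ko_table, mc_true = simulate_ko_table(catalog, modules, config, rng_ko)
        ko_table.to_csv(outdir / "ko_table.tsv", sep="\t")
        truth.module_completeness_true = mc_true
        stages.append("ko_table")

    truth.write(outdir / "truth")
    manifest = {
        "config": json.loads(json.dumps(config.__dict__, default=list)),
        "stages": stages,
        "noiseless": noiseless,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return truth
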