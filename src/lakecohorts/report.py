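"""End-to-end pipeline driver and per-run report assembly.

``run_pipeline`` chains the analysis stages — abundance profiling (or the
ground-truth abundances for depth-free runs), prevalence, SparCC network,
cohort extraction, environmental preference, metabolic scoring and summary
regressions — over a simulated (or externally supplied) run directory, and
persists every stage output as TSV. ``build_report`` re-reads the persisted
stage outputs and assembles the summary tables, so every report number is
recomputable from disk with no hidden state.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import cohorts as co
from . import metabolism as mb
from . import sparcc as sp
from . import stats as st
from .catalog import GenomeRecord, filter_quality
from .errors import DependencyError

__all__ = ["run_pipeline", "build_report"]


def _read_catalog(run_dir: Path) -> list[GenomeRecord]:
    df = pd.read_csv(run_dir / "catalog.tsv", sep="\t", index_col=0)
    return [
        GenomeRecord(
            id=str(idx),
            assembly_size=float(r["assembly_size"]),
            completeness=float(r["completeness"]),
            contamination=float(r["contamination"]),
            taxonomy=str(r.get("taxonomy", "")),
            derivation=str(r.get("derivation", "MAG")),
            environment=str(r.get("environment", "")),
        )
        for idx, r in df.iterrows()
    ]


def run_pipeline(
    run_dir: str | Path,
    seed: int = 0,
    use_depth: bool | None = None,
    n_boot: int = 100,
    n_perm: int = 200,
    rewiring_iters: int = 1000,
    rho_min: float = 0.4,
    alpha: float = 0.05,
    min_cohort_size: int = 6,
    central_fraction: float = 0.8,
    window: int = 100,
) -> dict:
    """Run abundance -> network -> cohorts -> metabolism on a run directory.

    ``use_depth`` controls whether abundances are recomputed from BedGraph
    depth profiles (default: yes when a ``bedgraph/`` directory exists) or
    taken from the simulator's ground-truth table. Outputs land under
    ``<run_dir>/analysis/`` with a manifest of every parameter.
    """
    run_dir = Path(run_dir)
    out = run_dir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    if use_depth is None:
        use_depth = (run_dir / "bedgraph").is_dir()

    if use_depth:
        if not (run_dir / "bedgraph").is_dir():
            raise DependencyError(f"no bedgraph/ directory under {run_dir}")
        matrix, sample_stats = ab.abundance_from_run(
            run_dir, central_fraction=central_fraction, window=window
        )
        sample_stats.to_csv(out / "sample_stats.tsv", sep="\t")
    else:
        truth_file = run_dir / "truth" / "true_abundance.tsv"
        if not truth_file.exists():
            raise DependencyError(f"neither depth profiles nor {truth_file} available")
        matrix = ab.AbundanceMatrix(pd.read_csv(truth_file, sep="\t", index_col=0))
    matrix.abundance.to_csv(out / "abundance.tsv", sep="\t")
    long = matrix.abundance.rename_axis("species").reset_index().melt(
        id_vars="species", var_name="sample", value_name="relative_abundance"
    )
    long.to_csv(out / "abundance_long.tsv", sep="\t", index=False)

    prev = ab.prevalence_and_average(matrix)
    prev_all = ab.prevalence_and_average(matrix, include_zeros=True)
    prev["avg_relative_abundance_all_samples_pct"] = prev_all["avg_relative_abundance_pct"]
    prev.to_csv(out / "prevalence.tsv", sep="\t")

    filtered = sp.prefilter(matrix.abundance)
    rho = sp.sparcc_correlation(filtered.abundance, seed=seed)
    pvals = sp.bootstrap_pvalues(filtered.abundance, rho, n_boot=n_boot, seed=seed)
    edges = sp.build_edges(rho, pvals, rho_min=rho_min, alpha=alpha)
    rho.to_csv(out / "sparcc_rho.tsv", sep="\t")
    pvals.to_csv(out / "sparcc_pvalues.tsv", sep="\t")
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    graph = co.graph_from_edges(edges)
    if graph.number_of_edges() > 0:
        communities, q = co.cluster_greedy_modularity(graph)
        q_p = co.modularity_significance(
            graph, n_perm=n_perm, rewiring_iters=rewiring_iters, seed=seed
        )
    else:
        communities, q, q_p = [], 0.0, 1.0
    cohort_of = co.extract_cohorts(communities, min_size=min_cohort_size)
    cohort_table = pd.Series(cohort_of, name="cohort").rename_axis("species").sort_index()
    cohort_table.to_csv(out / "cohorts.tsv", sep="\t")
    if graph.number_of_nodes() > 0:
        co.export_graphml(graph, cohort_of, out / "network.graphml")
    degree = co.degree_within_cohort(graph, cohort_of)
    degree.rename_axis("species").to_csv(out / "degree_within_cohort.tsv", sep="\t")

    env_file = run_dir / "env_params.tsv"
    if env_file.exists() and any(v != "background" for v in cohort_of.values()):
        env = pd.read_csv(env_file, sep="\t", index_col=0)
        pref = co.environmental_preference(matrix, cohort_of, env)
        pref.rename_axis("cohort").to_csv(out / "environmental_preference.tsv", sep="\t")

    manifest = {
        "seed": seed,
        "use_depth": use_depth,
        "central_fraction": central_fraction,
        "detection_rule": "tad80 > 0",
        "prefilter": {"min_samples": 3, "min_overall_abundance": 1e-4, "overall": "mean"},
        "n_boot": n_boot,
        "rho_min": rho_min,
        "alpha": alpha,
        "n_perm": n_perm,
        "rewiring_iters": rewiring_iters,
        "min_cohort_size": min_cohort_size,
        "modularity_q": q,
        "modularity_q_pvalue": q_p,
        "n_network_species": int(filtered.abundance.shape[0]),
        "n_edges": int(len(edges)),
        "n_cohorts": len({v for v in cohort_of.values() if v != "background"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def build_report(run_dir: str | Path, hq_completeness: float = 0.9) -> Path:
    """Assemble the per-run summary tables from persisted stage outputs.

    Emits, under ``<run_dir>/report/``: genome size vs prevalence and vs
    average relative abundance regressions, genus size-variability, cohort
    membership / connectedness / environmental preference summaries,
    retained-module completeness summaries per category, and KO-density
    regressions. Sections whose upstream stage did not run are emitted
    empty. Fixed inputs give byte-identical output.
    """
    run_dir = Path(run_dir)
    analysis = run_dir / "analysis"
    if not analysis.is_dir():
        raise DependencyError(f"run the pipeline first: no {analysis}")
    rep = run_dir / "report"
    rep.mkdir(exist_ok=True)

    catalog = _read_catalog(run_dir)
    est_size = pd.Series({g.id: g.estimated_size for g in catalog}, name="estimated_size_bp")
    prev = pd.read_csv(analysis / "prevalence.tsv", sep="\t", index_col=0)

    # --- genome size vs prevalence / average abundance -------------------
    fits = []
    common = est_size.index.intersection(prev.index)
    for response in ("prevalence_pct", "avg_relative_abundance_pct"):
        y = prev.loc[common, response]
        fit = st.linear_fit(est_size.loc[common] / 1e6, y)
        fits.append(
            {
                "response": response,
                "slope_per_mbp": fit.slope,
                "intercept": fit.intercept,
                "pearson_r": fit.pearson_r,
                "r_squared": fit.r_squared,
                "n": int(len(common)),
            }
        )
    pd.DataFrame(fits).to_csv(rep / "size_regressions.tsv", sep="\t", index=False)

    # --- genus variability ----------------------------------------------
    from .catalog import SpeciesCluster, genus_variability

    clusters = [SpeciesCluster(representative=g.id, members={g.id}) for g in catalog]
    gv = genus_variability(clusters, catalog)
    pd.DataFrame([asdict(v) for v in gv]).to_csv(rep / "genus_variability.tsv", sep="\t", index=False)

    # --- cohorts ---------------------------------------------------------
    cohorts_file = analysis / "cohorts.tsv"
    rows = []
    if cohorts_file.exists():
        cohort_of = pd.read_csv(cohorts_file, sep="\t", index_col=0)["cohort"]
        deg_file = analysis / "degree_within_cohort.tsv"
        degree = (
            pd.read_csv(deg_file, sep="\t", index_col=0)["degree_within_cohort"]
            if deg_file.exists()
            else pd.Series(dtype=float)
        )
        for label in sorted(set(cohort_of) - {"background"}):
            members = cohort_of.index[cohort_of == label]
            rows.append(
                {
                    "cohort": label,
                    "n_members": int(len(members)),
                    "mean_degree_within": float(degree.reindex(members).mean()) if len(degree) else np.nan,
                    "mean_estimated_size_mbp": float(est_size.reindex(members).mean() / 1e6),
                    "mean_prevalence_pct": float(prev.loc[prev.index.intersection(members), "prevalence_pct"].mean()),
                }
            )
    pd.DataFrame(rows, columns=["cohort", "n_members", "mean_degree_within", "mean_estimated_size_mbp", "mean_prevalence_pct"]).to_csv(
        rep / "cohort_summary.tsv", sep="\t", index=False
    )
    pref_file = analysis / "environmental_preference.tsv"
    if pref_file.exists():
        pd.read_csv(pref_file, sep="\t", index_col=0).to_csv(rep / "environmental_preference.tsv", sep="\t")

    # --- metabolic potential (high-quality genomes only) ----------------
    mod_file, ko_file = run_dir / "modules.tsv", run_dir / "ko_table.tsv"
    mod_rows, density_rows = [], []
    if mod_file.exists() and ko_file.exists():
        mods_df = pd.read_csv(mod_file, sep="\t")
        modules = [
            mb.parse_definition(r.definition, module_id=r.module_id, category=r.category)
            for r in mods_df.itertuples()
        ]
        ko_table = pd.read_csv(ko_file, sep="\t", index_col=0)
        hq_ids = [g.id for g in filter_quality(catalog, min_completeness=hq_completeness)]
        ko_hq = ko_table.loc[ko_table.index.intersection(hq_ids)]
        if len(ko_hq):
            comp = mb.completeness_matrix(modules, ko_hq)
            comp.to_csv(rep / "module_completeness_hq.tsv", sep="\t")
            kept = set(mb.filter_modules(comp))
            by_cat: dict[str, list[str]] = {}
            for m in modules:
                if m.module_id in kept:
                    by_cat.setdefault(m.category, []).append(m.module_id)
            for cat, ids in sorted(by_cat.items()):
                sub = comp[ids]
                mean_comp = sub.mean(axis=1)
                fit = st.linear_fit(est_size.reindex(sub.index) / 1e6, mean_comp)
                mod_rows.append(
                    {
                        "category": cat,
                        "n_modules_retained": len(ids),
                        "mean_completeness_pct": float(sub.to_numpy().mean()),
                        "size_slope_pct_per_mbp": fit.slope,
                        "size_pearson_r": fit.pearson_r,
                    }
                )
            # KO density vs size, with and without zero-density genomes
            category_map = {
                cat: {ko for m in modules if m.category == cat for ko in m.kos()}
                for cat in sorted({m.category for m in modules})
            }
            for cat, members in category_map.items():
                dens = pd.Series(
                    {
                        gid: mb.kos_per_mbp(
                            set(ko_hq.columns[ko_hq.loc[gid].astype(bool)]),
                            {cat: members},
                            est_size[gid],
                        )[cat]
                        for gid in ko_hq.index
                    }
                )
                for variant, mask in (("all", dens.notna()), ("nonzero", dens > 0)):
                    if mask.sum() >= 3 and est_size.reindex(dens.index[mask]).nunique() > 1:
                        fit = st.linear_fit(est_size.reindex(dens.index[mask]) / 1e6, dens[mask])
                        density_rows.append(
                            {
                                "category": cat,
                                "variant": variant,
                                "n": int(mask.sum()),
                                "slope_per_mbp": fit.slope,
                                "pearson_r": fit.pearson_r,
                            }
                        )
    pd.DataFrame(mod_rows, columns=["category", "n_modules_retained", "mean_completeness_pct", "size_slope_pct_per_mbp", "size_pearson_r"]).to_csv(
        rep / "module_summary.tsv", sep="\t", index=False
    )
    pd.DataFrame(density_rows, columns=["category", "variant", "n", "slope_per_mbp", "pearson_r"]).to_csv(
        rep / "ko_density_regressions.tsv", sep="\t", index=False
    )

    manifest = json.loads((analysis / "manifest.json").read_text())
    manifest["report_sections"] = sorted(p.name for p in rep.iterdir())
    (rep / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return rep
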