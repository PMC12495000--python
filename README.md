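# lakecohorts

Quantitative machinery for genome-resolved freshwater metagenomics: from
per-genome sequencing depth profiles to relative abundance and prevalence,
compositional co-occurrence networks, cohorts of co-varying species with
environmental preference scores, and KEGG-module metabolic complementarity —
plus a synthetic community generator with exported ground truth so the whole
chain is testable without any external sequencing data.

## The scientific problem

Free-living freshwater prokaryotes with streamlined genomes (often < 2 Mbp)
tend to be both highly prevalent across lakes and highly abundant within
them, yet many lack complete biosynthetic pathways for amino acids,
nucleotides and vitamins. The Black Queen picture is that such auxotrophs
persist by co-occurring with neighbours that retain the lost functions.
Testing this at scale requires a chain of estimators:

* **Genome size** of an incomplete assembly is estimated as
  `assembly_size / completeness`; genomes are dereplicated into species
  clusters at the ANI > 95% boundary with the highest-quality member as
  representative.
* **Relative abundance** of a genome in a metagenome is
  `TAD80 / genome equivalents`, where TAD80 (truncated average depth) is the
  mean positional depth after discarding the top and bottom 10% of
  positions, and genome equivalents = total sequenced bp / average genome
  size of the community (estimated from universal single-copy marker-gene
  hits, `AGS_m = c_m · total_bp / hits_m`). **Prevalence** is the percentage
  of samples in which a species is detected.
* **Co-occurrence** between species is inferred with the SparCC estimator,
  which works on log-ratio variances `t_ij = Var(log x_i/x_j)` (invariant to
  compositional closure) and solves the sparse basis-variance system for
  correlations `ρ_ij = (ω_i + ω_j − t_ij) / 2√(ω_i ω_j)`; significance comes
  from a permutation bootstrap, and only positive edges (ρ > 0.4, p < 0.05)
  are kept.
* **Cohorts** — groups of species that co-vary in space and time — are
  communities of ≥ 6 members found by greedy modularity (CNM) clustering,
  with modularity Q tested against degree-preserving rewired null networks.
  Each cohort gets an abundance-weighted environmental preference (z-scored
  absolute latitude, temperature, oxygen).
* **Metabolic potential** is scored from KEGG module DEFINITION strings: a
  parser for the step/alternative/complex/optional grammar, per-genome
  completeness, the two module-retention filters (one complete genome;
  ≥ 20% of genomes non-zero), and KO-per-Mbp functional densities.

## Worked example

```python
import lakecohorts as lc

cfg = lc.SimulationConfig(seed=1)        # 4 cohorts x 25 species + 120 background, 200 samples
catalog, sizes = lc.simulate.simulate_catalog(cfg)
abundance, labels, env = lc.simulate.simulate_abundances(catalog, cfg)

filtered = lc.prefilter(abundance)                         # >= 3 samples, mean RA > 1e-4
rho   = lc.sparcc_correlation(filtered.abundance)
pvals = lc.bootstrap_pvalues(filtered.abundance, rho, n_boot=100, seed=1)
edges = lc.build_edges(rho, pvals)                         # rho > 0.4, p < 0.05

from lakecohorts.cohorts import graph_from_edges
g = graph_from_edges(edges)
communities, q = lc.cluster_greedy_modularity(g)
cohort_of = lc.extract_cohorts(communities)                # >= 6 members
pref = lc.environmental_preference(lc.AbundanceMatrix(abundance), cohort_of, env)
print(f"{len(edges)} edges, Q = {q:.3f}, "
      f"{len({v for v in cohort_of.values() if v != 'background'})} cohorts")
print(pref.round(2))
```

prints

```
1175 edges, Q = 0.750, 4 cohorts
          abs_latitude  temperature  oxygen
cohort_1          0.07         0.03   -0.01
cohort_2          0.03         0.00   -0.09
cohort_3          0.09        -0.00    0.00
cohort_4         -0.06         0.00    0.46
```

All four planted cohorts are recovered (Q = 0.75, adjusted Rand index 0.99
against the planted labels), and the oxygen-coupled cohort — here recovered
as `cohort_4` — stands out with an oxygen preference of +0.46 z-units while
every other preference sits near the baseline.

The same stages are exposed as a CLI:
`lakecohorts simulate | derep | abundance | network | cohorts | metabolism |
pipeline | report` (see `lakecohorts --help`).

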