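# Methods

This note documents the models, estimators and design choices behind
`lakecohorts`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not demonstrate.

## 1. Genome catalog

**Size estimation.** For an assembly of size `A` bp with completeness
`c ∈ (0, 1]` (a fraction, as produced by marker-based quality estimators),
the estimated genome size is `A / c`. The estimator is exact when the
missing fraction of the genome is size-representative; it is monotone
decreasing in `c` and equals `A` for complete genomes.

**Quality tiers.** Medium-to-high quality means completeness strictly
greater than 50% and contamination strictly less than 5%; the high-quality
tier used for metabolic scoring tightens completeness to > 90%. Strict
inequalities are used at both boundaries.

**Dereplication.** Genomes are grouped into species clusters at an average
nucleotide identity boundary (default ANI > 95%, strict). The clustering
rule is quality-sorted greedy seeding: rank genomes by completeness
(descending), contamination (ascending), assembly size (descending), id
(ascending); each unassigned genome in rank order seeds a cluster and
absorbs every still-unassigned genome above the ANI threshold *to the
seed*. The seed is the cluster representative. Greedy seeding was chosen
over single-linkage connected components because the latter chains A–B–C
merges through intermediate genomes even when A and C are below the
boundary; the threshold and ranking are configurable. Missing pairs in the
ANI table are treated as below threshold.

**Genus variability.** For genera with at least five species clusters, the
mean, sample standard deviation (n−1), variance (sd²) and coefficient of
variation (CV = sd/mean × 100) of representative estimated sizes are
reported. Smaller genera are omitted, not errors.

## 2. Abundance profiling

**TAD.** The truncated average depth of a positional depth vector of
length `L` with central fraction `f` (default 0.8) sorts the depths, drops
`k = floor(((1−f)/2)·L)` entries from each end, and averages the rest.
Zero-depth positions are part of the distribution — a genome covered over
only half its length is penalised through its low quantiles, which is the
intended behaviour of the statistic. The floor is guarded with a 1e-9
epsilon because `(1−0.8)/2·L` is not exactly representable in binary
floating point. Depth profiles are windowed (default 100 bp windows,
configurable): TAD is quantile-based, so resolution only needs to be fine
relative to the 10% trim fraction.

**Average genome size and genome equivalents.** Universal single-copy
marker families hit a metagenome's reads at a rate inversely proportional
to the community's average genome size (AGS), so per family `m` with
calibration constant `c_m`: `AGS_m = c_m · total_bp / hits_m`; the point
estimate is the median over families with non-zero hits. Genome
equivalents `GE = total_bp / AGS` convert depth into relative abundance:
`RA = TAD80 / GE`.

**Detection and prevalence.** A species is detected in a sample when
TAD80 > 0 (the default rule; a breadth-of-coverage floor can be swapped
in). Prevalence is 100 × detected / total samples. The average relative
abundance is taken over *detected* samples by default; the
all-samples-with-zeros variant is available via `include_zeros=True` and
both are written by the pipeline. Never-detected species report average 0
with an explicit flag.

## 3. SparCC co-occurrence

Relative abundances are compositional; Pearson correlation on them is
biased by closure. The SparCC estimator works from log-ratio variances
`t_ij = Var(log(x_i/x_j))`, writes `t_ij = ω_i + ω_j − 2ρ_ij√(ω_iω_j)` in
terms of latent basis variances ω and correlations ρ, and — assuming the
correlation network is sparse so that Σ_j ρ_ij ≈ 0 — solves the linear
system `[11ᵀ + (D−2)I] ω = t·1` for ω, then
`ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_iω_j))`, clipped to [−1, 1]. Pairs that
violate sparsity are handled by iteratively excluding the most strongly
correlated pair above an exclusion threshold (default |ρ| > 0.1) from the
system and re-solving, up to D−4 exclusions. At least 4 species and 3
samples are required (below that the basis system is under-determined).

Design choices:

* **Input form.** The estimator takes relative abundances directly (the
  pipeline feeds it mapping-derived fractions): columns are renormalised
  once and a single deterministic pass is made. With integer counts
  (`counts=True`), each of the 50 inner iterations draws per-sample
  fractions from a Dirichlet posterior (+1 pseudo-count) and the median
  (configurable to mean) over iterations is returned.
* **Zeros** are replaced by half the smallest positive value before taking
  logs, then columns are re-closed.
* **Prefilter.** Species enter the network when detected in ≥ 3 samples
  with overall relative abundance > 1e-4. "Overall" is read as the mean
  across all samples; max and sum are selectable alternatives.
* **Bootstrap p-values.** Every species' vector is permuted across samples
  independently, the estimator re-run, and `p_ij` is the raw proportion of
  null correlations ≥ the observed one (one-sided upper tail — only
  positive co-occurrences are retained downstream). No +1 pseudo-count is
  added, so a correlation above every null draw gets exactly p = 0. Child
  seeds are derived per bootstrap from the root seed, making results
  independent of execution order and parallelisation.
* **Edges.** Kept when ρ > 0.4 and p < 0.05, both strict; negative edges
  are never kept.

## 4. Cohorts

**Clustering.** Communities are found by Clauset–Newman–Moore greedy
modularity agglomeration (via `networkx.community.greedy_modularity_communities`),
returning the partition at maximum `Q = Σ_c [e_c/m − (d_c/2m)²]`. The graph
is unweighted (edges are already thresholded); tie-breaking among equal
modularity gains follows the library's deterministic ordering, so a fixed
graph always yields the same partition. An edgeless graph yields singleton
communities with Q = 0.

**Significance.** The observed Q is compared against null networks
produced by degree-preserving rewiring: each null applies a fixed number
of *attempted* double-edge swaps (default 1000; swaps creating loops or
parallel edges are rejected, so every degree is preserved exactly —
asserted per permutation), and is re-clustered from scratch — the stricter
null, as opposed to re-scoring the observed partition. p is the raw
proportion of null Q ≥ observed Q over 500 permutations by default. Graphs
with fewer than two edges cannot be rewired and report p = 1 with a
warning.

**Cohorts.** Communities with ≥ 6 members are labelled cohort 1..k by
descending size (ties by smallest member id); smaller communities are
background. Within-cohort connectedness is the node degree in the cohort's
induced subgraph — cross-cohort edges do not count.

**Environmental preference.** Each covariate is z-scored across samples
(sample sd) *before* weighting; the preference of cohort c is the weighted
average of the z-scores with weights `w_cs = Σ_{g∈c} RA[g, s]`. This makes
preferences an above/below-baseline contrast comparable across covariates
and bounded by the extreme z-scores (convex combination). The
opposite order (weight first, standardise after) is available via
`zscore_first=False`. Missing covariate values are dropped pairwise per
covariate; a zero-variance covariate is reported as NaN.

## 5. Metabolic potential

**Grammar.** Module DEFINITION strings are parsed by recursive descent
with precedence (tightest first) minus > plus > comma > space; parentheses
create explicit group nodes. A group is a single all-or-nothing unit
wherever it appears, including when it spans the whole definition.

**Completeness.** Default scoring ("strict-steps") is top-level step
granularity: 100 × satisfied non-optional steps / total non-optional
steps, where alternatives are satisfied by any branch, complexes by all
non-optional subunits, and groups all-or-nothing. Minus-prefixed
components are optional: they never appear in denominators and never
reduce completeness. A "fractional" mode (sequences average their parts,
alternatives take the best branch) matches the style of annotation suites
that give partial credit for nested structure; the strict mode is the
default because step counts are then integers and hand-checkable. A module
whose steps are all optional has undefined completeness (NaN).

**Retention filters.** A module is retained when (1) at least one genome
reaches 100% completeness and (2) at least 20% of genomes have
completeness > 0%. Combined multi-module pathways aggregate by unweighted
mean of member completeness by default; a pooled step-weighted variant is
selectable. KO densities are distinct KOs per category divided by
estimated genome size in Mbp; regressions are run both with and without
zero-density genomes, since the two variants answer different questions
(compaction vs complete loss).

## 6. Synthetic community generator

The generator emulates the statistical structure of a freshwater genome
catalog profiled across many metagenomes; its defaults are the package's
reference study conditions.

* **Catalog.** True genome lengths are log-uniform over 1–5 Mbp;
  completeness uniform on [0.5, 1], contamination uniform on [0, 0.05];
  assembly size is exactly `true length × completeness`, so the size
  estimator recovers truth exactly and downstream size effects are
  controlled. Species are organised into genera of 8 so the ≥ 5-member
  genus statistics are exercised. Taxonomy strings are synthetic labels,
  not phylogenetically realistic.
* **Abundances.** 4 planted cohorts of 25 species on 120 background
  species across 200 samples. Per cohort and sample a latent log-normal
  factor (sd 1.0) is shared by members with loading 1.0 plus species noise
  (log-sd 0.5); the first cohort's factor is a monotone logistic response
  of the oxygen covariate (steepness 1.7, rescaled to comparable log-sd),
  which plants an environmental preference contrast. Species-level
  baselines (log-sd 1.0) give the long-tailed rank-abundance curve in
  which most species sit far below the mean share. Columns are closed to
  sum to one. The log-normal form is a modelling choice — real abundance
  distributions are characterised here only by their long tail.
* **Depth.** Genome equivalents are fixed at `coverage_target × n_species`
  (default mean coverage 10×); expected coverage of genome g in sample s
  is `RA[g,s] × GE`, and positional depth per 100-bp window is Poisson
  with that mean. Total reads are rounded to whole reads first so
  `total_bp` is an exact multiple of the read length and the noiseless
  mode is exactly self-consistent. Marker hits are Binomial(total_reads,
  `c_m·L_read/AGS_true`) — the simplest model in which hit counts are
  inversely proportional to AGS. Zero-abundance species still get an
  explicit all-zero BedGraph record so prevalence denominators are
  unambiguous.
* **KO repertoires.** Per-KO carriage probability follows a logistic link
  in true genome size (default slope 1.5 per Mbp around the mid-range
  size) plus a per-KO prevalence offset (sd 0.8), so mean biosynthetic
  completeness rises with genome size. Module-completeness ground truth is
  computed with the same evaluator the analysis uses. The synthetic module
  catalog (32 modules over amino acid / nucleotide / vitamin / other
  categories) is generated from the grammar and is a stand-in, not a copy
  of any curated database.

Fixed seeds give byte-identical outputs, including BedGraph files.

**What passing these simulations shows — and what it does not.** Recovery
of planted cohorts demonstrates that the estimator chain (closure →
log-ratio correlation → bootstrap → modularity) is internally consistent
and calibrated at realistic effect sizes; it does not demonstrate that
real freshwater communities satisfy the generative assumptions (log-normal
factors, sample-independent noise, Poisson depth free of mappability
artefacts, taxonomically unstructured KO gain). In particular, real depth
profiles carry conserved-region pile-ups that TAD trimming mitigates but
the Poisson simulation does not generate.

## 7. Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the smallest at
which each statistical property is unambiguous: oracle equivalence at 20
species × 200 samples (agreement to 1e-6), i.i.d. nulls at 500 samples,
bootstrap calibration at 200 replicates × 100 bootstraps, Erdős–Rényi
modularity calibration at 200 graphs × 39 permutations (39 makes the
p < 0.05 event probability exactly 5% under exchangeability), and
end-to-end recovery over 5 seeds at the reference configuration.
Degenerate inputs (empty vectors, zero variance, all-optional modules,
edgeless graphs, unrewirable graphs) return errors, NaN, or warnings as
documented per function rather than silently propagating.

## Known limitations

* SparCC's sparsity assumption breaks when most pairs are strongly
  correlated; the exclusion loop mitigates moderate violations only.
* The rewiring null holds degrees fixed but not higher-order structure.
* The compact letter display uses a greedy assignment; with intransitive
  significance patterns letters are a readable summary, not a unique one.
* Marker-gene AGS calibration constants are taken as known; real
  single-copy-gene estimators carry calibration error that the simulation
  only models as Binomial sampling.
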