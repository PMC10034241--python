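# Methods

## Incidence model

Let `b` index 10-year age bins partitioning [0, 50) (half-open; age exactly
50 is excluded, a documented reading of the inclusive-sounding "0–50" and
configurable via `age_cap`). The institutional cohort, filtered to carriers
of a liver-cancer inclusion code (default C22.0/C22.7) with none of a
configurable chronic-liver-inflammation exclusion list, gives per-bin counts
`k_b` validated FLC out of `n_b` total. Patients whose label is UNKNOWN or
OTHER count in `n_b` but never `k_b`: chart validation is the only accepted
source of FLC truth.

The FLC proportion per bin is modeled binomially with a conjugate Beta
prior, default Beta(1, 1) (a Jeffreys Beta(0.5, 0.5) is one argument away);
no empirical information enters the prior, so thin bins stay diffuse. The
update accepts real-valued counts (generalized conjugacy) so renormalized
totals from the distance analysis need no rounding.

The claims side is summarized per bin by the sample mean and SD (ddof = 1)
of annual counts over the reference years (default 2017–2019; 2020 is
deliberately not a default because pandemic-era claims are confounded).
Fewer than two years leaves the SD undefined and is an error unless the SD
is supplied directly.

Each Monte Carlo replicate (default 10,000) draws, per bin,
`N ~ Normal(μ, σ)` truncated at 0 and rounded (the count model named by the
mean/SD summary; truncation and rounding are our documented choices),
`p ~ Beta(α, β)`, and `F ~ Binomial(N, p)` — fully generative; an
`expectation` mode replaces the binomial draw with `N·p` for variance
decomposition. Replicate totals are scaled by a `coverage_factor` mapping
claims enrollment to the national population; no published value exists for
this factor, so it is an explicit config input (synthetic runs use 3.0,
i.e., claims covering a third of the country). The reported SD is the
spread of coverage-scaled replicate totals; it propagates posterior,
count-model and binomial uncertainty but no uncertainty in the coverage
factor itself.

## Referral-distance sensitivity

Patient zip3 prefixes map to centroids (synthetic geography places centroids
on a meridian so haversine distances are exact by construction; real
gazetteers can be supplied in the same table format). Distance is haversine
with Earth radius 3958.8 mi. Restriction keeps mappable patients with
`d < x` strictly; patients with absent or unmappable zip3 are returned
separately, never dropped.

Renormalization: per bin, the fraction `f_b` of mappable non-FLC patients
surviving the cut (a pooled-fraction mode exists for sensitivity; empty bins
fall back to the pooled value) scales the missing-zip patients added back:
`n_total ← retained + f_b · lost`, real-valued. FLC counts are unchanged by
default — in the study no missing-zip patient carried FLC, and the synthetic
cohort generator reproduces that condition (missing zips only afflict
non-FLC patients); an `flc_lost` term exists for sensitivity analyses. At a
threshold beyond the maximum distance this construction restores the
original counts exactly, and the same-seed simulation is bit-identical.

The sweep re-fits posteriors and re-simulates per threshold with a derived
seed (`seed + rank` in descending-threshold order) so any single threshold
can be recomputed alone.

## Hyperammonemia encounter assembly and clustering

Within each encounter the maximum ammonia is located (earliest draw wins a
tie); encounters below the threshold — default 50, interpreted as µmol/L
since no unit is standard in coded lab streams — are excluded. For each of
the 10 CMP analytes the measurement nearest in absolute time to the
ammonia peak is taken; an exact tie prefers the earlier draw. Any analyte
absent within the window (default 7 days) excludes the encounter, with a
per-encounter audit reason (`below_threshold`, `incomplete_panel`,
`no_ammonia`).

The feature matrix is the full 11-variable panel (max ammonia + 10 CMP);
`include_ammonia=False` drops the selection variable to probe its
contribution. Columns are z-scored with the population SD (ddof = 0, the
single-cell-style convention; switchable), and a constant column is an
error naming the analyte. PCA keeps `min(n_pcs, n_features, n − 1)`
components — a nominal 40 components caps at 11, a full-rank rotation that
preserves Euclidean geometry exactly. The kNN graph (default k = 5,
Minkowski p = 2; the metric family is configurable) is union-symmetrized
and unweighted, with no self-edges; Leiden optimizes the
RB-configuration modularity at the given resolution (default 0.2),
deterministic given the seed, and labels are renumbered by descending
cluster size. A k-means baseline is provided for comparison only. UMAP
embedding is optional visualization; no result depends on it.

## Enrichment testing

Encounters (not unique patients) are the analysis unit. For each diagnosis
and each cluster — and each pooled pair of clusters when enabled; pooling
into a single 2×2 table is our reading of a "combined" two-cluster test — a
2×2 table (in-cluster × diagnosis) is tested with the two-sided Fisher exact
test (probability-at-most-observed convention, with the conventional
1 + 1e-7 relative tie gate). The multiplicative correction multiplies
single-cluster p-values by k and pair p-values by C(k, 2), capped at 1.
This is Bonferroni-style control retained for fidelity to the source
analysis despite its "FDR" label there; `method="bh"` applies genuine
Benjamini–Hochberg within each family. A literal pair-factor override
exists because some analyses use 2k rather than C(k, 2). The odds ratio is
ad/bc, with ∞ when bc = 0 < ad and 0 when ad = 0 < bc.

## Synthetic study conditions

The generator defaults define the test-bed, chosen once:

* cohort n = 5000, uniform age distribution over five bins, FLC proportions
  (0.5, 0.3, 0.1, 0.02, 0.005) — a steep AYA-skewed gradient whose analytic
  expectation is computable in closed form; comorbidity-code rates 0.30
  (HCC) and 0.18 (FLC, the share of validated cases stringent exclusions
  remove); missing-zip fraction 0.11 (89% zip recovery), non-FLC only;
* claims years 2017–2019, per-bin means (150, 300, 900, 2500, 6000) rising
  with age as liver cancer does, CV 0.05, counts drawn
  `round(max(0, Normal(μ, cv·μ)))` — Normal is an assumption, not a
  published distributional fact;
* lab mixture: four diagonal-covariance Gaussian archetypes over the 11
  analytes (near-normal panel, extreme hyperammonemia, hepatocellular
  injury, renal/metabolic), 600 encounters in the pipeline default and 400
  with 10-SD separation in recovery tests; ammonia is floored at the
  selection threshold so every generated encounter qualifies;
* diagnosis labels are drawn first from marginal weights, then the cluster
  is drawn from the diagnosis's own cluster distribution (rows sum to 1),
  so planted odds ratios are analytically computable; FLC and UCD prefer
  the near-normal and extreme-ammonia archetypes, mirroring the
  co-enrichment pattern the method should detect.

What the generator does not emulate: analyte correlation within clusters
(diagonal covariance keeps recovery tests interpretable; a correlated
extension would exercise PCA harder), realistic ICD ontologies or US
geography, temporal lab dynamics beyond a fixed two-hour panel offset, and
repeat encounters per patient. Passing recovery tests therefore shows the
machinery is correct under the stated model, not that real hyperammonemia
phenotypes are this separable.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng`; identical
  parameters and seed give bit-identical outputs, and pipeline stages use
  CRC32-derived per-stage seeds below 2³¹.
* Bins are consumed in ascending age order regardless of input order;
  posterior/claims bin sets must match exactly.
* Monte Carlo sizes (10,000 replicates; 5000-patient cohorts; 400–600
  encounters) keep every check comfortably inside a desktop run while
  leaving recovery margins of several SDs.
* The pair-correction factor C(k, 2) and the exact-ratio reporting of
  validated-case fractions are deliberate: where a source's printed
  arithmetic conflicts with its definitions, the package computes the
  defined quantity and exposes an override rather than hard-coding the
  printed number.
* Known limitations: the coverage factor is exogenous and unmodeled; the
  Normal count model is an assumption; Leiden determinism is per-seed, not
  per-platform-independent beyond igraph/leidenalg guarantees; the
  renormalizer presumes missing-zip patients share the age-bin composition
  of the mappable lost population.
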