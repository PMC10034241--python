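# flcpipe

Estimating the incidence of a rare cancer from routine clinical data, and
phenotyping one of its metabolic complications.

Fibrolamellar liver cancer (FLC) is a rare primary liver cancer of
adolescents and young adults. Registry data (SEER) put its incidence near
0.02 per 100,000 — likely an underestimate, because FLC lacks a specific
ICD-10 code and is often misclassified as conventional hepatocellular
carcinoma (HCC). `flcpipe` implements a tiered analysis that addresses this:

1. **Incidence arm** — validated FLC/HCC labels from a single institution's
   EMR give, per 10-year age bin *b* below 50, counts `(k_b, n_b)`. With a
   Beta(α₀, β₀) prior and binomial likelihood, the FLC proportion has
   posterior `p_b ~ Beta(α₀ + k_b, β₀ + n_b − k_b)`. A national claims table
   supplies mean and SD of annual comorbidity-excluded liver-cancer counts
   per bin; each of 10,000 Monte Carlo replicates draws
   `N_b ~ round(max(0, Normal(μ_b, σ_b)))`, `p_b` from the posterior, and
   `F_b ~ Binomial(N_b, p_b)`. The coverage-scaled replicate totals
   `c·Σ_b F_b` yield the annual national estimate (mean ± SD) and a
   per-100,000 rate.
2. **Referral-distance arm** — tertiary centers attract rare-disease
   referrals from far away, inflating the observed FLC proportion. Patients
   are mapped to zip3 centroids, the cohort is restricted to haversine
   distance `d < x` from the center for a sweep of thresholds, missing-zip
   patients are added back per age bin in proportion to the surviving
   fraction of mappable controls, and the simulation is re-run per
   threshold.
3. **Hyperammonemia arm** — encounters whose maximum blood ammonia is
   ≥ 50 µmol/L are assembled into a complete 11-analyte matrix (ammonia plus
   the 10 metabolic-panel analytes, each taken at the draw nearest the
   ammonia peak, all within 7 days). The z-scored matrix goes through
   PCA → kNN graph (Minkowski metric, k = 5) → Leiden (resolution 0.2), and
   diagnosis enrichment per cluster (and per cluster pair) is tested with
   Fisher's exact test, corrected by ×k (singles) or ×C(k,2) (pairs), with a
   Benjamini–Hochberg alternative.

The real EMR/claims inputs are restricted-access, so a first-class
`simulate` module generates all inputs with known ground truth (planted age
structure, cluster mixture, diagnosis enrichment), making every stage
testable end to end.

## Worked example

```bash
python examples/01_cohort_and_incidence.py
```

```
per-bin FLC / total:
    0-10:  511 / 1023
   10-20:  308 / 1017
   20-30:   92 /  975
   30-40:   27 / 1016
   40-50:    4 /  969

estimated annual cases : 1055 ± 84
per-100k incidence     : 0.320
analytic expectation   : 1005
rate for 602 cases     : 0.185 per 100k
```

A 5000-patient synthetic cohort with planted bin proportions
(0.5, 0.3, 0.1, 0.02, 0.005) is binned, fitted, and extrapolated onto claims
means (150…6000) with coverage factor 3. The Monte Carlo mean tracks the
analytic expectation `c·Σ_b μ_b p_b = 1005` well within its reported SD; the
last line is the rate arithmetic for a 602-case national estimate over a
325.4M population. The other examples cover the distance sweep
(`02`), encounter assembly + clustering (`03`), enrichment testing (`04`),
and the one-command pipeline (`05`), which is also available as
`flcpipe run --out DIR --seed N` on the shell.

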