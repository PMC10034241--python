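"""Bayesian inference of age-specific FLC proportions and Monte Carlo
extrapolation to annual national incidence.

Model
-----
For each age bin b, the validated cohort gives ``n_flc`` fibrolamellar cases
out of ``n_total`` liver-cancer patients.  With a Beta(a0, b0) prior and a
binomial likelihood the FLC proportion has the conjugate posterior

    p_b | data ~ Beta(a0 + n_flc, b0 + n_total - n_flc),

so thinly populated bins stay appropriately uncertain.  The national claims
population supplies, per bin, the mean and SD of annual comorbidity-excluded
liver-cancer counts across reference years.  Each Monte Carlo replicate draws
a count N_b ~ Normal(mean_b, sd_b) (truncated at 0, rounded), a proportion
p_b from the posterior, and F_b ~ Binomial(N_b, p_b); the replicate total
sum_b F_b, scaled by a coverage factor for claims-to-national extrapolation,
yields the posterior-predictive distribution of annual cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AgeBin, AgeBinCounts


@dataclass(frozen=True)
class ProportionPosterior:
    """Beta posterior over one age bin's FLC/HCC proportion."""

    bin: AgeBin
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class ClaimsBinStats:
    """Per-bin mean/SD of annual claims counts across reference years."""

    bin: AgeBin
    mean_count: float
    sd_count: float
    years_used: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mean_count < 0 or self.sd_count < 0:
            raise ValueError("mean_count and sd_count must be >= 0")
        if not self.years_used:
            raise ValueError("years_used must be non-empty")


@dataclass(frozen=True)
class IncidenceEstimate:
    """Monte Carlo posterior summary of annual national cases."""

    mean_cases: float
    sd_cases: float
    per_100k: float
    n_reps: int
    coverage_factor: float
    population: int
    seed: int
    per_rep_totals: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


def fit_posterior(
    counts: AgeBinCounts, prior_alpha: float = 1.0, prior_beta: float = 1.0
) -> ProportionPosterior:
    """Conjugate Beta update from one bin's tallies.

    Accepts real-valued tallies (generalized conjugacy) so that renormalized,
    non-integer totals from the referral-distance analysis update the
    posterior without rounding.  Empty bins return the prior unchanged.
    """
    if prior_alpha <= 0 or prior_beta <= 0:
        raise ValueError("prior parameters must be positive")
    if counts.n_flc > counts.n_total:
        raise ValueError("n_flc cannot exceed n_total")
    return ProportionPosterior(
        bin=counts.bin,
        alpha=prior_alpha + counts.n_flc,
        beta=prior_beta + (counts.n_total - counts.n_flc),
    )


def fit_posteriors(
    counts: Sequence[AgeBinCounts], prior_alpha: float = 1.0, prior_beta: float = 1.0
) -> list[ProportionPosterior]:
    return [fit_posterior(c, prior_alpha, prior_beta) for c in counts]


def claims_stats(
    claims: pd.DataFrame,
    bins: Sequence[AgeBin],
    years: Sequence[int],
) -> list[ClaimsBinStats]:
    """Per-bin sample mean and SD (ddof=1) of annual counts over listed years.

    ``claims`` must have columns ``year``, ``age_bin`` (bin label such as
    "0-10") and ``count``.  Requesting fewer than two years leaves the SD
    undefined and raises.
    """
    years = sorted(int(y) for y in years)
    if len(years) < 2:
        raise ValueError("need >= 2 years to estimate an SD; supply sd_count explicitly instead")
    present = set(claims["year"].unique())
    missing = [y for y in years if y not in present]
    if missing:
        raise ValueError(f"requested years absent from claims table: {missing}")
    sub = claims[claims["year"].isin(years)]
    out = []
    for b in bins:
        vals = sub.loc[sub["age_bin"] == b.label, "count"].to_numpy(dtype=float)
        if len(vals) != len(years):
            raise ValueError(f"bin {b.label}: expected one count per year, got {len(vals)}")
        out.append(
            ClaimsBinStats(
                bin=b,
                mean_count=float(np.mean(vals)),
                sd_count=float(np.std(vals, ddof=1)),
                years_used=tuple(years),
            )
        )
    return out


def simulate_incidence(
    posteriors: Sequence[ProportionPosterior],
    stats: Sequence[ClaimsBinStats],
    n_reps: int = 10_000,
    coverage_factor: float = 1.0,
    population: int = 0,
    seed: int = 0,
    mode: str = "binomial",
    keep_reps: bool = False,
) -> IncidenceEstimate:
    """Monte Carlo posterior-predictive simulation of annual cases.

    Per replicate and bin: N ~ Normal(mean, sd) truncated at 0 and rounded;
    p ~ Beta(alpha, beta); F ~ Binomial(N, p) (or F = N*p in ``expectation``
    mode, which strips the binomial sampling layer for variance-decomposition
    studies).  Replicate totals are scaled by ``coverage_factor`` before
    summarizing.  Deterministic given seed; bins are consumed in ascending
    age order regardless of input order.
    """
    if coverage_factor <= 0:
        raise ValueError("coverage_factor must be > 0")
    if mode not in ("binomial", "expectation"):
        raise ValueError("mode must be 'binomial' or 'expectation'")
    post = sorted(posteriors, key=lambda p: p.bin.lower)
    st = sorted(stats, key=lambda s: s.bin.lower)
    if [p.bin for p in post] != [s.bin for s in st]:
        raise ValueError("posteriors and claims stats must cover identical bins")

    rng = np.random.default_rng(seed)
    totals = np.zeros(n_reps)
    for p, s in zip(post, st):
        if s.sd_count > 0:
            n = rng.normal(s.mean_count, s.sd_count, size=n_reps)
        else:
            n = np.full(n_reps, s.mean_count)
        n = np.rint(np.clip(n, 0.0, None)).astype(np.int64)
        prop = rng.beta(p.alpha, p.beta, size=n_reps)
        if mode == "binomial":
            totals += rng.binomial(n, prop)
        else:
            totals += n * prop
    scaled = coverage_factor * totals
    mean_cases = float(np.mean(scaled))
    sd_cases = float(np.std(scaled, ddof=1)) if n_reps > 1 else 0.0
    return IncidenceEstimate(
        mean_cases=mean_cases,
        sd_cases=sd_cases,
        per_100k=cases_to_rate(mean_cases, population) if population > 0 else float("nan"),
        n_reps=n_reps,
        coverage_factor=coverage_factor,
        population=population,
        seed=seed,
        per_rep_totals=scaled if keep_reps else None,
    )


def cases_to_rate(mean_cases: float, population: int) -> float:
    """Annual cases converted to a per-100,000 incidence rate."""
    if population <= 0:
        raise ValueError("population must be > 0")
    return 100_000.0 * mean_cases / population


def fold_vs_reference(rate: float, reference_rate: float) -> int:
    """Integer fold-difference between an incidence rate and a registry baseline."""
    if reference_rate <= 0:
        raise ValueError("reference_rate must be > 0")
    return round(rate / reference_rate)
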