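"""Synthetic-data generators for every pipeline input.

The study's real inputs (an institutional EMR cohort, a national claims
table, a hyperammonemia lab-event stream) are restricted-access, so this
module generates stand-ins with the statistical structure the analysis
assumes: an age-structured two-disease cohort with comorbidity codes and
coarse zip geography, year-varying claims counts per age bin, and an
11-analyte lab matrix drawn from a mixture of cluster-specific Gaussians
with diagnosis labels preferentially assigned to clusters.  Every generator
is deterministic given its seed, and true labels are returned for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ammonia_cluster import AMMONIA, N_PANEL, PANEL_ANALYTES, LabEncounter
from .cohort import AgeBin, PatientRecord

DEFAULT_INCLUDE_CODE = "C22.0"
DEFAULT_EXCLUSION_CODES = ("B18.2", "K74.60", "B18.1")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic EMR cohort.

    ``age_bin_flc_proportions`` gives, per age bin, the probability that a
    liver-cancer patient in that bin is fibrolamellar rather than
    conventional HCC.  ``zip3_pool`` pairs zip3 strings with sampling
    weights; ``missing_zip_fraction`` is the chance a patient's zip3 is
    unrecorded.
    """

    n_patients: int
    age_bin_flc_proportions: Mapping[AgeBin, float]
    age_distribution: Mapping[AgeBin, float]
    comorbidity_code_rate_hcc: float = 0.0
    comorbidity_code_rate_flc: float = 0.0
    zip3_pool: Sequence[tuple[str, float]] = ()
    missing_zip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for b, p in self.age_bin_flc_proportions.items():
            _check_prob(f"flc proportion for {b.label}", p)
        _check_prob("comorbidity_code_rate_hcc", self.comorbidity_code_rate_hcc)
        _check_prob("comorbidity_code_rate_flc", self.comorbidity_code_rate_flc)
        _check_prob("missing_zip_fraction", self.missing_zip_fraction)
        tot = sum(self.age_distribution.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"age_distribution must sum to 1, got {tot}")
        if set(self.age_distribution) != set(self.age_bin_flc_proportions):
            raise ValueError("age_distribution and age_bin_flc_proportions must share bins")


def generate_emr_cohort(params: CohortSimParams) -> list[PatientRecord]:
    """Draw an age-structured FLC/HCC cohort with inclusion/exclusion codes.

    Every patient carries a liver-cancer inclusion code; an exclusion
    (chronic-liver-inflammation) code is added with the label-specific rate;
    zip3 is drawn from the weighted pool or left missing.  Missing zips only
    afflict non-FLC patients, emulating the study condition that every
    validated FLC case had recoverable zip data (the missing-zip
    renormalizer relies on this; see geo module).
    """
    rng = np.random.default_rng(params.seed)
    bins = sorted(params.age_distribution, key=lambda b: b.lower)
    bin_probs = np.asarray([params.age_distribution[b] for b in bins])
    patients: list[PatientRecord] = []
    zips = [z for z, _ in params.zip3_pool]
    zw = np.asarray([w for _, w in params.zip3_pool], dtype=float)
    if len(zips) and zw.sum() <= 0:
        raise ValueError("zip3_pool weights must have positive sum")
    if len(zips):
        zw = zw / zw.sum()
    for i in range(params.n_patients):
        b = bins[rng.choice(len(bins), p=bin_probs)]
        age = int(rng.integers(b.lower, b.upper))
        is_flc = rng.random() < params.age_bin_flc_proportions[b]
        label = "FLC" if is_flc else "HCC"
        codes = {DEFAULT_INCLUDE_CODE}
        rate = params.comorbidity_code_rate_flc if is_flc else params.comorbidity_code_rate_hcc
        if rng.random() < rate:
            codes.add(DEFAULT_EXCLUSION_CODES[int(rng.integers(len(DEFAULT_EXCLUSION_CODES)))])
        zip3: Optional[str] = None
        if len(zips):
            drop = (not is_flc) and rng.random() < params.missing_zip_fraction
            if not drop:
                zip3 = zips[rng.choice(len(zips), p=zw)]
        patients.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                age_at_diagnosis=age,
                codes=frozenset(codes),
                label=label,
                zip3=zip3,
            )
        )
    return patients


@dataclass(frozen=True)
class ClaimsSimParams:
    """Parameters of the synthetic national claims table.

    Annual comorbidity-excluded liver-cancer counts per age bin are drawn
    Normal(mean, cv * mean), rounded and floored at zero — the same Normal
    form the downstream simulation assumes for these counts.
    """

    years: Sequence[int]
    bin_mean_counts: Mapping[AgeBin, float]
    bin_dispersion: Mapping[AgeBin, float] | float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for b, m in self.bin_mean_counts.items():
            if m < 0:
                raise ValueError(f"mean count for {b.label} must be >= 0")
        for b in self.bin_mean_counts:
            if self.cv_for(b) < 0:
                raise ValueError(f"dispersion for {b.label} must be >= 0")

    def cv_for(self, b: AgeBin) -> float:
        if isinstance(self.bin_dispersion, Mapping):
            return float(self.bin_dispersion.get(b, 0.0))
        return float(self.bin_dispersion)


def generate_claims_counts(params: ClaimsSimParams) -> pd.DataFrame:
    """Year x age-bin table of non-negative integer counts."""
    rng = np.random.default_rng(params.seed)
    bins = sorted(params.bin_mean_counts, key=lambda b: b.lower)
    rows = []
    for year in params.years:
        for b in bins:
            mean = params.bin_mean_counts[b]
            cv = params.cv_for(b)
            if cv == 0:
                val = mean
            else:
                val = rng.normal(mean, cv * mean)
            rows.append({"year": int(year), "age_bin": b.label, "count": int(max(0, round(val)))})
    return pd.DataFrame(rows, columns=["year", "age_bin", "count"])


@dataclass(frozen=True)
class LabSimParams:
    """Parameters of the synthetic hyperammonemia lab matrix.

    Encounters are drawn from a mixture of diagonal-covariance Gaussians
    over the 11 panel analytes (ammonia first).  A diagnosis is drawn for
    each encounter from ``diagnosis_weights``; diagnoses listed in
    ``diagnosis_enrichment`` then place the encounter in a cluster according
    to their own cluster distribution (each row sums to 1), while all other
    encounters use ``cluster_weights``.  Ammonia values are floored at
    ``ammonia_floor`` so every generated encounter qualifies as
    hyperammonemic.
    """

    n_clusters: int
    cluster_centers: Sequence[Sequence[float]]
    cluster_scales: Sequence[Sequence[float]]
    cluster_weights: Sequence[float]
    n_encounters: int
    diagnosis_enrichment: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    diagnosis_weights: Mapping[str, float] = field(default_factory=dict)
    ammonia_floor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_encounters < 0:
            raise ValueError("n_clusters >= 1 and n_encounters >= 0 required")
        if len(self.cluster_centers) != self.n_clusters or len(self.cluster_scales) != self.n_clusters:
            raise ValueError("need one center and scale vector per cluster")
        for vec in list(self.cluster_centers) + list(self.cluster_scales):
            if len(vec) != N_PANEL:
                raise ValueError(f"center/scale vectors must have length {N_PANEL}")
        w = np.asarray(self.cluster_weights, dtype=float)
        if len(w) != self.n_clusters or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("cluster_weights must be a length-n_clusters simplex vector")
        for d, probs in self.diagnosis_enrichment.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"diagnosis {d!r} assignment probabilities must sum to 1")
            if any(not (0 <= c < self.n_clusters) for c in probs):
                raise ValueError(f"diagnosis {d!r} references an unknown cluster")
        dw = sum(self.diagnosis_weights.values())
        if self.diagnosis_weights and abs(dw - 1.0) > 1e-9:
            raise ValueError("diagnosis_weights must sum to 1")


def generate_lab_encounters(
    params: LabSimParams,
) -> tuple[list[LabEncounter], np.ndarray, list[str]]:
    """Draw encounters from the cluster mixture.

    Returns (encounters, true cluster labels, diagnosis labels).  Panel
    timestamps are deterministic: one encounter per day from 2015-01-01,
    CMP draws two hours after the ammonia peak.
    """
    rng = np.random.default_rng(params.seed)
    centers = np.asarray(params.cluster_centers, dtype=float)
    scales = np.asarray(params.cluster_scales, dtype=float)
    weights = np.asarray(params.cluster_weights, dtype=float)

    diag_names = list(params.diagnosis_weights)
    diag_probs = np.asarray([params.diagnosis_weights[d] for d in diag_names], dtype=float)

    encounters: list[LabEncounter] = []
    true_clusters = np.empty(params.n_encounters, dtype=int)
    diagnoses: list[str] = []
    t_base = pd.Timestamp("2015-01-01T08:00:00")
    ammonia_idx = PANEL_ANALYTES.index(AMMONIA)
    for i in range(params.n_encounters):
        diagnosis = (
            diag_names[rng.choice(len(diag_names), p=diag_probs)] if diag_names else "OTHER"
        )
        if diagnosis in params.diagnosis_enrichment:
            probs = params.diagnosis_enrichment[diagnosis]
            cl_ids = sorted(probs)
            z = cl_ids[rng.choice(len(cl_ids), p=np.asarray([probs[c] for c in cl_ids]))]
        else:
            z = int(rng.choice(params.n_clusters, p=weights))
        panel = rng.normal(centers[z], scales[z])
        panel[ammonia_idx] = max(params.ammonia_floor, panel[ammonia_idx])
        t0 = t_base + pd.Timedelta(days=i)
        times = tuple(
            t0 if a == AMMONIA else t0 + pd.Timedelta(hours=2) for a in PANEL_ANALYTES
        )
        encounters.append(
            LabEncounter(
                encounter_id=f"E{i:06d}",
                patient_id=f"LP{i:06d}",
                diagnosis_group=diagnosis,
                max_ammonia=float(panel[ammonia_idx]),
                panel=tuple(float(v) for v in panel),
                panel_times=times,
            )
        )
        true_clusters[i] = z
        diagnoses.append(diagnosis)
    return encounters, true_clusters, diagnoses


def lab_events_frame(
    encounters: Sequence[LabEncounter],
    extra_ammonia: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand encounters into a long lab-event stream (the labs.csv layout).

    Each encounter emits its max-ammonia draw plus the 10 CMP analytes at
    their recorded times; with ``extra_ammonia`` a strictly lower ammonia
    value is added six hours earlier, so downstream assembly must pick the
    maximum rather than the first event.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for e in encounters:
        for analyte, value, ts in zip(PANEL_ANALYTES, e.panel, e.panel_times):
            rows.append(
                {
                    "encounter_id": e.encounter_id,
                    "patient_id": e.patient_id,
                    "diagnosis": e.diagnosis_group,
                    "analyte": analyte,
                    "value": float(value),
                    "timestamp": ts,
                }
            )
        if extra_ammonia:
            t_amm = e.panel_times[PANEL_ANALYTES.index(AMMONIA)]
            rows.append(
                {
                    "encounter_id": e.encounter_id,
                    "patient_id": e.patient_id,
                    "diagnosis": e.diagnosis_group,
                    "analyte": AMMONIA,
                    "value": float(e.max_ammonia * rng.uniform(0.5, 0.95)),
                    "timestamp": t_amm - pd.Timedelta(hours=6),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["encounter_id", "patient_id", "diagnosis", "analyte", "value", "timestamp"],
    )
    return df.sort_values(["encounter_id", "timestamp"], kind="stable").reset_index(drop=True)


def generate_zip3_centroids(
    zip3_pool: Sequence[str],
    center_zip3: str,
    center_lat: float = 37.76,
    center_lon: float = -122.45,
    ring_miles: Optional[Mapping[str, float]] = None,
    spacing_miles: float = 50.0,
) -> pd.DataFrame:
    """Deterministic synthetic geography: zip3 centroids due north of a center.

    The designated ``center_zip3`` sits at the simulated tertiary center;
    every other zip3 is placed on the same meridian at its ``ring_miles``
    distance (or multiples of ``spacing_miles`` in pool order), so haversine
    distances to the center are exact by construction.
    """
    pool = list(zip3_pool)
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate zip3 in pool")
    miles_per_degree = 3958.8 * np.pi / 180.0
    rows = []
    k = 0
    for z in pool:
        if z == center_zip3:
            d = 0.0
        elif ring_miles is not None and z in ring_miles:
            d = float(ring_miles[z])
        else:
            k += 1
            d = k * spacing_miles
        rows.append({"zip3": z, "lat": center_lat + d / miles_per_degree, "lon": center_lon})
    return pd.DataFrame(rows, columns=["zip3", "lat", "lon"])
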