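"""End-to-end orchestration: simulate → cohort → incidence → sweep → cluster → enrich.

``run_pipeline`` executes the requested stages in dependency order on a
synthetic dataset (or user-supplied CSVs laid out the same way), logs every
effective parameter and derived seed, and writes a single reproducible
report: rerunning with an identical config yields byte-identical artifacts.
Per-stage seeds are derived from the global seed and the stage name (CRC32),
so any stage can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .ammonia_cluster import (
    ClusterConfig,
    assemble_encounters,
    cluster_encounters,
    cluster_profiles,
    encounters_frame,
)
from .cohort import AgeBin, CodePolicy, apply_code_policy, bin_counts, decade_bins
from .enrichment import enrich_all
from .geo import Zip3Centroid, centroid_table, incidence_distance_sweep, sweep_frame
from .incidence import claims_stats, fit_posteriors, simulate_incidence
from .simulate import (
    ClaimsSimParams,
    CohortSimParams,
    LabSimParams,
    generate_claims_counts,
    generate_emr_cohort,
    generate_lab_encounters,
    generate_zip3_centroids,
    lab_events_frame,
)

logger = logging.getLogger("flcpipe")

ALL_STAGES = ("simulate", "cohort", "incidence", "sweep", "cluster", "enrich")

#: Default synthetic study conditions (see docs/methods.md for rationale).
DEFAULT_FLC_PROPORTIONS = {"0-10": 0.5, "10-20": 0.3, "20-30": 0.1, "30-40": 0.02, "40-50": 0.005}
DEFAULT_AGE_DISTRIBUTION = {"0-10": 0.2, "10-20": 0.2, "20-30": 0.2, "30-40": 0.2, "40-50": 0.2}
DEFAULT_CLAIMS_MEANS = {"0-10": 150.0, "10-20": 300.0, "20-30": 900.0, "30-40": 2500.0, "40-50": 6000.0}

# Cluster archetypes for the synthetic lab matrix, analyte order:
# ammonia, sodium, potassium, chloride, bicarbonate, BUN, creatinine,
# ALT, AST, total_bilirubin, alkaline_phosphatase
DEFAULT_LAB_CENTERS = [
    [80, 139, 4.0, 103, 24, 14, 0.9, 35, 40, 1.0, 95],     # near-normal CMP
    [290, 136, 3.8, 100, 22, 12, 0.8, 45, 55, 1.2, 110],   # extreme hyperammonemia
    [95, 131, 4.4, 95, 18, 28, 1.1, 900, 1300, 8.0, 260],  # hepatocellular injury
    [85, 134, 5.2, 98, 15, 70, 4.5, 40, 50, 1.0, 130],     # renal/metabolic
]
DEFAULT_LAB_SCALES = [
    [12, 2.5, 0.3, 2.5, 1.8, 3.5, 0.15, 9, 11, 0.25, 16],
    [35, 2.8, 0.3, 2.6, 2.0, 3.2, 0.14, 13, 16, 0.3, 20],
    [16, 3.0, 0.35, 2.8, 2.0, 6.0, 0.25, 180, 260, 2.0, 50],
    [14, 2.8, 0.4, 2.7, 2.0, 12.0, 0.9, 10, 13, 0.25, 24],
]
DEFAULT_DIAGNOSIS_WEIGHTS = {
    "FLC": 0.03,
    "UCD": 0.12,
    "HCC_cirrhotic": 0.10,
    "HCC_noncirrhotic": 0.08,
    "CRC": 0.10,
    "OTHER": 0.57,
}
# FLC and UCD prefer the near-normal-CMP and extreme-ammonia clusters,
# mirroring the co-enrichment pattern the analysis is designed to detect.
DEFAULT_DIAGNOSIS_ENRICHMENT = {
    "FLC": {0: 0.45, 1: 0.45, 2: 0.05, 3: 0.05},
    "UCD": {0: 0.40, 1: 0.50, 2: 0.05, 3: 0.05},
    "HCC_cirrhotic": {0: 0.10, 1: 0.05, 2: 0.75, 3: 0.10},
    "CRC": {0: 0.10, 1: 0.05, 2: 0.70, 3: 0.15},
    "HCC_noncirrhotic": {0: 0.25, 1: 0.10, 2: 0.40, 3: 0.25},
}


@dataclass
class RunConfig:
    """Every effective parameter of a pipeline run; no hidden defaults."""

    out_dir: str
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    age_cap: int = 50
    # simulate: cohort
    n_patients: int = 5000
    flc_proportions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FLC_PROPORTIONS))
    age_distribution: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION))
    comorbidity_code_rate_hcc: float = 0.30
    comorbidity_code_rate_flc: float = 0.18
    zip3_pool: Sequence[Sequence[Any]] = (
        ("941", 0.35), ("945", 0.25), ("956", 0.15), ("895", 0.10),
        ("900", 0.08), ("100", 0.04), ("330", 0.03),
    )
    missing_zip_fraction: float = 0.11
    # simulate: claims
    years: Sequence[int] = (2017, 2018, 2019)
    claims_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLAIMS_MEANS))
    claims_cv: float = 0.05
    # simulate: labs + geography
    n_encounters: int = 600
    lab_centers: Sequence[Sequence[float]] = tuple(tuple(r) for r in DEFAULT_LAB_CENTERS)
    lab_scales: Sequence[Sequence[float]] = tuple(tuple(r) for r in DEFAULT_LAB_SCALES)
    cluster_weights: Sequence[float] = (0.35, 0.15, 0.30, 0.20)
    diagnosis_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_WEIGHTS))
    diagnosis_enrichment: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_DIAGNOSIS_ENRICHMENT.items()}
    )
    center_zip3: str = "941"
    zip3_ring_miles: Mapping[str, float] = field(
        default_factory=lambda: {"945": 30.0, "956": 90.0, "895": 220.0, "900": 380.0, "100": 2570.0, "330": 2580.0}
    )
    # cohort
    exclude_codes: Sequence[str] = ("B18.1", "B18.2", "K74.60")
    # incidence
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    n_reps: int = 10_000
    coverage_factor: float = 3.0
    population: int = 330_000_000
    # sweep
    thresholds: Sequence[float] = (2000.0, 1000.0, 500.0, 250.0, 100.0)
    # cluster
    ammonia_threshold: float = 50.0
    window_days: float = 7.0
    n_neighbors: int = 5
    n_pcs: int = 40
    minkowski_p: float = 2.0
    resolution: float = 0.2
    # enrich
    include_pairs: bool = True
    enrich_method: str = "multiplicative"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = io.read_json(path)
        if "diagnosis_enrichment" in raw:  # JSON object keys are strings
            raw["diagnosis_enrichment"] = {
                d: {int(c): p for c, p in probs.items()}
                for d, probs in raw["diagnosis_enrichment"].items()
            }
        if "zip3_pool" in raw:
            raw["zip3_pool"] = [(str(z), float(w)) for z, w in raw["zip3_pool"]]
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32(stage) xor global, below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0x7FFFFFFF)) % (2**31)


def _bins_from_labels(labels: Mapping[str, float]) -> dict[AgeBin, float]:
    out = {}
    for lab, v in labels.items():
        lo, hi = lab.split("-")
        out[AgeBin(int(lo), int(hi))] = float(v)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a reproducible report.

    Outputs land under ``config.out_dir``: the synthetic CSVs, per-stage
    JSON/CSV results, ``run_audit.json`` (seeds + artifact hashes) and
    ``report.json`` (the machine-readable summary returned by this function).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    bins = decade_bins(config.age_cap)
    report: dict[str, Any] = {"config": _config_echo(config), "stages": {}}
    audit: dict[str, Any] = {"seed": config.seed, "stage_seeds": {}, "artifacts": {}}

    def _record(stage: str, *paths: Path) -> None:
        for p in paths:
            audit["artifacts"][p.name] = _sha256(p)

    try:
        if "simulate" in stages:
            s = stage_seed(config.seed, "simulate")
            audit["stage_seeds"]["simulate"] = s
            patients = generate_emr_cohort(
                CohortSimParams(
                    n_patients=config.n_patients,
                    age_bin_flc_proportions=_bins_from_labels(config.flc_proportions),
                    age_distribution=_bins_from_labels(config.age_distribution),
                    comorbidity_code_rate_hcc=config.comorbidity_code_rate_hcc,
                    comorbidity_code_rate_flc=config.comorbidity_code_rate_flc,
                    zip3_pool=[(z, w) for z, w in config.zip3_pool],
                    missing_zip_fraction=config.missing_zip_fraction,
                    seed=s,
                )
            )
            io.write_patients(patients, out / "patients.csv")
            claims = generate_claims_counts(
                ClaimsSimParams(
                    years=config.years,
                    bin_mean_counts=_bins_from_labels(config.claims_means),
                    bin_dispersion=config.claims_cv,
                    seed=s + 1,
                )
            )
            io.write_claims(claims, out / "claims.csv")
            encounters, true_clusters, diagnoses = generate_lab_encounters(
                LabSimParams(
                    n_clusters=len(config.lab_centers),
                    cluster_centers=config.lab_centers,
                    cluster_scales=config.lab_scales,
                    cluster_weights=config.cluster_weights,
                    n_encounters=config.n_encounters,
                    diagnosis_enrichment=config.diagnosis_enrichment,
                    diagnosis_weights=config.diagnosis_weights,
                    ammonia_floor=config.ammonia_threshold,
                    seed=s + 2,
                )
            )
            io.write_labs(lab_events_frame(encounters, seed=s + 3), out / "labs.csv")
            centroids = generate_zip3_centroids(
                [z for z, _ in config.zip3_pool],
                center_zip3=config.center_zip3,
                ring_miles=config.zip3_ring_miles,
            )
            io.write_centroids(centroids, out / "zip3_centroids.csv")
            io.write_json(
                {
                    "true_clusters": true_clusters.tolist(),
                    "diagnoses": diagnoses,
                    "seed": s,
                },
                out / "truth.json",
            )
            _record(
                "simulate",
                out / "patients.csv", out / "claims.csv", out / "labs.csv",
                out / "zip3_centroids.csv", out / "truth.json",
            )
            report["stages"]["simulate"] = {
                "n_patients": len(patients),
                "n_encounters": len(encounters),
                "seed": s,
            }
            logger.info("simulate: %d patients, %d encounters", len(patients), len(encounters))

        patients = io.read_patients(out / "patients.csv") if (set(stages) & {"cohort", "incidence", "sweep"}) else []

        counts = None
        if "cohort" in stages:
            policy = CodePolicy(exclude_codes=frozenset(config.exclude_codes))
            filtered, policy_audit = apply_code_policy(patients, policy)
            counts = bin_counts(filtered, bins, config.age_cap)
            summary = {
                "policy_audit": policy_audit,
                "bin_counts": [
                    {"bin": c.bin.label, "n_flc": c.n_flc, "n_total": c.n_total} for c in counts
                ],
            }
            io.write_json(summary, out / "cohort_summary.json")
            _record("cohort", out / "cohort_summary.json")
            report["stages"]["cohort"] = summary
            patients = filtered
            logger.info("cohort: retained %d patients", policy_audit["n_retained"])

        st = None
        if "incidence" in stages or "sweep" in stages:
            claims = io.read_claims(out / "claims.csv")
            st = claims_stats(claims, bins, config.years)

        if "incidence" in stages:
            if counts is None:
                summary = io.read_json(out / "cohort_summary.json")
                counts = [_row_to_counts(row) for row in summary["bin_counts"]]
            s = stage_seed(config.seed, "incidence")
            audit["stage_seeds"]["incidence"] = s
            est = simulate_incidence(
                fit_posteriors(counts, config.prior_alpha, config.prior_beta),
                st,
                n_reps=config.n_reps,
                coverage_factor=config.coverage_factor,
                population=config.population,
                seed=s,
            )
            inc = {
                "mean_cases": est.mean_cases,
                "sd_cases": est.sd_cases,
                "per_100k": est.per_100k,
                "n_reps": est.n_reps,
                "coverage_factor": est.coverage_factor,
                "population": est.population,
                "seed": est.seed,
            }
            io.write_json(inc, out / "incidence.json")
            _record("incidence", out / "incidence.json")
            report["stages"]["incidence"] = inc
            logger.info("incidence: %.1f ± %.1f cases/yr", est.mean_cases, est.sd_cases)

        if "sweep" in stages:
            s = stage_seed(config.seed, "sweep")
            audit["stage_seeds"]["sweep"] = s
            cents = centroid_table(io.read_centroids(out / "zip3_centroids.csv"))
            center = cents[config.center_zip3]
            results = incidence_distance_sweep(
                patients,
                cents,
                center,
                config.thresholds,
                st,
                bins,
                age_cap=config.age_cap,
                prior_alpha=config.prior_alpha,
                prior_beta=config.prior_beta,
                n_reps=config.n_reps,
                coverage_factor=config.coverage_factor,
                population=config.population,
                seed=s,
            )
            sf = sweep_frame(results)
            sf.to_csv(out / "sweep.csv", index=False)
            _record("sweep", out / "sweep.csv")
            report["stages"]["sweep"] = sf.to_dict(orient="records")
            logger.info("sweep: %d thresholds", len(results))

        labels = None
        encounters = None
        if "cluster" in stages:
            s = stage_seed(config.seed, "cluster")
            audit["stage_seeds"]["cluster"] = s
            events = io.read_labs(out / "labs.csv")
            encounters, assembly_audit = assemble_encounters(
                events, config.ammonia_threshold, config.window_days
            )
            cfg = ClusterConfig(
                n_neighbors=config.n_neighbors,
                n_pcs=config.n_pcs,
                minkowski_p=config.minkowski_p,
                resolution=config.resolution,
                seed=s,
            )
            res = cluster_encounters(encounters, cfg)
            labels = res.labels
            encounters_frame(encounters, labels).to_csv(out / "encounters.csv", index=False)
            pd.DataFrame(
                {"encounter_id": res.encounter_ids, "label": res.labels}
            ).to_csv(out / "clusters.csv", index=False)
            cluster_profiles(encounters, labels).to_csv(out / "profiles.csv", index=False)
            _record("cluster", out / "encounters.csv", out / "clusters.csv", out / "profiles.csv")
            report["stages"]["cluster"] = {
                "n_encounters": len(encounters),
                "n_excluded": len(assembly_audit),
                "n_clusters": res.n_clusters,
                "seed": s,
            }
            logger.info("cluster: %d encounters -> %d clusters", len(encounters), res.n_clusters)

        if "enrich" in stages:
            if labels is None or encounters is None:
                enc_df = pd.read_csv(out / "encounters.csv")
                labels = enc_df["cluster"].to_numpy()
                diagnoses = enc_df["diagnosis"].tolist()
            else:
                diagnoses = [e.diagnosis_group for e in encounters]
            results = enrich_all(
                labels,
                diagnoses,
                include_pairs=config.include_pairs,
                method=config.enrich_method,
                background="OTHER",
            )
            df = pd.DataFrame(
                {
                    "diagnosis": [r.diagnosis for r in results],
                    "clusters": ["+".join(map(str, sorted(r.clusters))) for r in results],
                    "a": [r.table.a for r in results],
                    "b": [r.table.b for r in results],
                    "c": [r.table.c for r in results],
                    "d": [r.table.d for r in results],
                    "odds_ratio": [r.odds_ratio for r in results],
                    "p": [r.p_value for r in results],
                    "p_adj": [r.p_adjusted for r in results],
                    "factor": [r.correction_factor for r in results],
                }
            )
            df.to_csv(out / "enrichment.csv", index=False)
            _record("enrich", out / "enrichment.csv")
            report["stages"]["enrich"] = {
                "n_tests": len(results),
                "top": df.head(5).to_dict(orient="records"),
            }
            logger.info("enrich: %d tests", len(results))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    io.write_json(audit, out / "run_audit.json")
    io.write_json(report, out / "report.json")
    return report


def _row_to_counts(row: Mapping[str, Any]):
    from .cohort import AgeBinCounts

    lo, hi = str(row["bin"]).split("-")
    return AgeBinCounts(bin=AgeBin(int(lo), int(hi)), n_flc=row["n_flc"], n_total=row["n_total"])


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["stages"] = list(config.stages)
    return echo
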