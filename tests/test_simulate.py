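import math

import numpy as np
import pandas as pd
import pytest

from flcpipe import io
from flcpipe.ammonia_cluster import PANEL_ANALYTES
from flcpipe.cohort import bin_counts, decade_bins
from flcpipe.geo import Zip3Centroid, centroid_table, distance_miles
from flcpipe.simulate import (
    ClaimsSimParams,
    CohortSimParams,
    LabSimParams,
    generate_claims_counts,
    generate_emr_cohort,
    generate_lab_encounters,
    generate_zip3_centroids,
    lab_events_frame,
)
from conftest import make_cohort_params, separated_lab_params


class TestCohortGenerator:
    def test_zero_patients(self, bins5, recovery_props):
        params = make_cohort_params(bins5, recovery_props, n=0)
        assert generate_emr_cohort(params) == []

    def test_forced_flc_labels(self, bins5):
        params = make_cohort_params(bins5, {b: 1.0 for b in bins5}, n=100)
        assert all(p.label == "FLC" for p in generate_emr_cohort(params))

    def test_flc_fraction_within_binomial_noise(self, bins5):
        # an overall under-50 FLC share of 21% of liver-cancer cases
        p = 0.21
        n = 20_000
        params = make_cohort_params(bins5, {b: p for b in bins5}, n=n, seed=123)
        cohort = generate_emr_cohort(params)
        frac = sum(1 for x in cohort if x.label == "FLC") / n
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_inclusion_code_always_present(self, bins5, recovery_props):
        params = make_cohort_params(bins5, recovery_props, n=200, seed=5,
                                    comorbidity_code_rate_hcc=0.5)
        assert all("C22.0" in p.codes for p in generate_emr_cohort(params))

    def test_exclusion_rate_respected(self, bins5):
        params = make_cohort_params(bins5, {b: 0.0 for b in bins5}, n=10_000, seed=7,
                                    comorbidity_code_rate_hcc=0.3)
        cohort = generate_emr_cohort(params)
        rate = sum(1 for p in cohort if len(p.codes) > 1) / len(cohort)
        assert abs(rate - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 10_000)

    def test_missing_zip_spares_flc(self, bins5):
        params = make_cohort_params(
            bins5, {b: 0.5 for b in bins5}, n=2000, seed=9,
            zip3_pool=[("941", 1.0)], missing_zip_fraction=0.5,
        )
        cohort = generate_emr_cohort(params)
        assert all(p.zip3 is not None for p in cohort if p.label == "FLC")
        assert any(p.zip3 is None for p in cohort if p.label == "HCC")

    def test_deterministic_given_seed(self, bins5, recovery_props):
        params = make_cohort_params(bins5, recovery_props, n=300, seed=21,
                                    zip3_pool=[("941", 0.6), ("100", 0.4)],
                                    missing_zip_fraction=0.1)
        assert generate_emr_cohort(params) == generate_emr_cohort(params)

    def test_invalid_probability_rejected(self, bins5):
        with pytest.raises(ValueError):
            make_cohort_params(bins5, {b: 1.5 for b in bins5}, n=10)

    def test_age_distribution_must_sum_to_one(self, bins5, recovery_props):
        with pytest.raises(ValueError):
            CohortSimParams(
                n_patients=10,
                age_bin_flc_proportions=recovery_props,
                age_distribution={b: 0.5 for b in bins5},
            )


class TestClaimsGenerator:
    def test_zero_dispersion_returns_rounded_means(self, bins5, claims_means):
        params = ClaimsSimParams(years=[2017, 2018], bin_mean_counts=claims_means,
                                 bin_dispersion=0.0)
        df = generate_claims_counts(params)
        for b in bins5:
            vals = df.loc[df["age_bin"] == b.label, "count"]
            assert (vals == round(claims_means[b])).all()

    def test_counts_within_three_sd(self, bins5):
        params = ClaimsSimParams(years=[2017, 2018, 2019],
                                 bin_mean_counts={bins5[0]: 1000.0},
                                 bin_dispersion=0.1, seed=3)
        df = generate_claims_counts(params)
        assert df["count"].between(700, 1300).all()

    def test_empty_years(self, claims_means):
        df = generate_claims_counts(ClaimsSimParams(years=[], bin_mean_counts=claims_means))
        assert df.empty

    def test_counts_are_nonnegative_integers(self, bins5):
        params = ClaimsSimParams(years=range(2000, 2020),
                                 bin_mean_counts={bins5[0]: 2.0},
                                 bin_dispersion=3.0, seed=1)
        df = generate_claims_counts(params)
        assert (df["count"] >= 0).all()
        assert df["count"].dtype.kind == "i"


class TestLabGenerator:
    def test_single_cluster_labels_identical(self):
        params = separated_lab_params(n_clusters=1, n=50)
        _, truth, _ = generate_lab_encounters(params)
        assert (truth == 0).all()

    def test_ammonia_floor_enforced(self):
        params = separated_lab_params(n=200, seed=2)
        enc, _, _ = generate_lab_encounters(params)
        assert all(e.max_ammonia >= params.ammonia_floor for e in enc)

    def test_planted_diagnosis_fraction(self):
        p = 0.9
        params = separated_lab_params(
            n=2000, seed=6,
            diagnosis_weights={"UCD": 0.5, "OTHER": 0.5},
            diagnosis_enrichment={"UCD": {0: p, 1: 0.1 / 3, 2: 0.1 / 3, 3: 0.1 / 3}},
        )
        _, truth, diag = generate_lab_encounters(params)
        ucd = [t for t, d in zip(truth, diag) if d == "UCD"]
        frac = sum(1 for t in ucd if t == 0) / len(ucd)
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / len(ucd))

    def test_wrong_center_length_rejected(self):
        with pytest.raises(ValueError):
            LabSimParams(n_clusters=1, cluster_centers=[[1.0] * 5],
                         cluster_scales=[[1.0] * 5], cluster_weights=[1.0],
                         n_encounters=10)

    def test_deterministic_given_seed(self):
        params = separated_lab_params(n=40, seed=8)
        a = generate_lab_encounters(params)
        b = generate_lab_encounters(params)
        assert a[0] == b[0] and (a[1] == b[1]).all() and a[2] == b[2]


class TestGeography:
    def test_center_zip_distance_zero(self):
        df = generate_zip3_centroids(["941"], "941")
        c = centroid_table(df)["941"]
        assert distance_miles(c, c) == 0.0

    def test_one_degree_latitude_is_69_miles(self):
        a = Zip3Centroid("000", 0.0, 0.0)
        b = Zip3Centroid("001", 1.0, 0.0)
        assert distance_miles(a, b) == pytest.approx(69.09, abs=0.01)

    def test_ring_distances_exact(self):
        df = generate_zip3_centroids(["941", "945", "100"], "941",
                                     ring_miles={"945": 30.0, "100": 2500.0})
        t = centroid_table(df)
        assert distance_miles(t["941"], t["945"]) == pytest.approx(30.0, abs=1e-6)
        assert distance_miles(t["941"], t["100"]) == pytest.approx(2500.0, abs=1e-6)

    def test_empty_pool(self):
        assert generate_zip3_centroids([], "941").empty

    def test_duplicate_zip3_rejected(self):
        with pytest.raises(ValueError):
            generate_zip3_centroids(["941", "941"], "941")


class TestRoundTrips:
    def test_patients_csv(self, tmp_path, bins5, recovery_props):
        params = make_cohort_params(bins5, recovery_props, n=100, seed=1,
                                    zip3_pool=[("941", 1.0)], missing_zip_fraction=0.2)
        patients = generate_emr_cohort(params)
        io.write_patients(patients, tmp_path / "p.csv")
        assert io.read_patients(tmp_path / "p.csv") == patients

    def test_claims_csv(self, tmp_path, claims_means):
        df = generate_claims_counts(
            ClaimsSimParams(years=[2017, 2018, 2019], bin_mean_counts=claims_means,
                            bin_dispersion=0.1, seed=2)
        )
        io.write_claims(df, tmp_path / "c.csv")
        pd.testing.assert_frame_equal(io.read_claims(tmp_path / "c.csv"), df)

    def test_labs_csv(self, tmp_path):
        enc, _, _ = generate_lab_encounters(separated_lab_params(n=10, seed=3))
        events = lab_events_frame(enc, seed=4)
        io.write_labs(events, tmp_path / "l.csv")
        back = io.read_labs(tmp_path / "l.csv")
        pd.testing.assert_frame_equal(back, events)

    def test_centroids_csv(self, tmp_path):
        df = generate_zip3_centroids(["941", "945"], "941")
        io.write_centroids(df, tmp_path / "z.csv")
        pd.testing.assert_frame_equal(io.read_centroids(tmp_path / "z.csv"), df)


def test_event_stream_feeds_assembly_exactly():
    """Generated events reassemble into the generated encounters."""
    from flcpipe.ammonia_cluster import assemble_encounters

    enc, _, _ = generate_lab_encounters(separated_lab_params(n=25, seed=5))
    events = lab_events_frame(enc, seed=6)
    back, audit = assemble_encounters(events, ammonia_threshold=50.0, window_days=7.0)
    assert len(back) == len(enc) and audit.empty
    for e0, e1 in zip(enc, sorted(back, key=lambda e: e.encounter_id)):
        assert e0.encounter_id == e1.encounter_id
        assert e1.panel == pytest.approx(e0.panel)
        assert e1.max_ammonia == pytest.approx(e0.max_ammonia)
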