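import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from flcpipe.ammonia_cluster import (
    AMMONIA,
    PANEL_ANALYTES,
    ClusterConfig,
    assemble_encounters,
    build_graph,
    cluster_encounters,
    cluster_graph,
    cluster_profiles,
    encounter_matrix,
    kmeans_baseline,
    scale_matrix,
)
from flcpipe.simulate import generate_lab_encounters, lab_events_frame
from conftest import separated_lab_params

T0 = pd.Timestamp("2020-06-01T12:00:00")


def event(enc, analyte, value, hours=0.0, pid="p1"):
    return {
        "encounter_id": enc,
        "patient_id": pid,
        "analyte": analyte,
        "value": value,
        "timestamp": T0 + pd.Timedelta(hours=hours),
    }


def full_encounter(enc="e1", ammonia=80.0, skip=(), pid="p1", hours_offset=0.0):
    rows = [event(enc, AMMONIA, ammonia, hours=hours_offset, pid=pid)]
    for a in PANEL_ANALYTES:
        if a != AMMONIA and a not in skip:
            rows.append(event(enc, a, 1.0, hours=hours_offset + 1, pid=pid))
    return rows


class TestAssembly:
    def test_threshold_boundary(self):
        """Max ammonia 50 is retained (>= rule); 49 is excluded."""
        ev = pd.DataFrame(full_encounter("lo", ammonia=49.0) + full_encounter("hi", ammonia=50.0))
        enc, audit = assemble_encounters(ev)
        assert [e.encounter_id for e in enc] == ["hi"]
        assert audit.to_dict(orient="records") == [
            {"encounter_id": "lo", "reason": "below_threshold"}
        ]

    def test_incomplete_panel_excluded_with_reason(self):
        ev = pd.DataFrame(full_encounter("e1", skip=("sodium",)))
        enc, audit = assemble_encounters(ev)
        assert enc == []
        assert audit.iloc[0]["reason"] == "incomplete_panel"

    def test_nearest_measurement_wins(self):
        rows = full_encounter("e1")
        rows.append(event("e1", "sodium", 222.0, hours=2))     # +2 h: nearer
        rows = [r for r in rows if not (r["analyte"] == "sodium" and r["value"] == 1.0)]
        rows.append(event("e1", "sodium", 111.0, hours=-30))   # -30 h: farther
        enc, _ = assemble_encounters(pd.DataFrame(rows))
        assert enc[0].panel[PANEL_ANALYTES.index("sodium")] == 222.0

    def test_tie_prefers_earlier_measurement(self):
        rows = [r for r in full_encounter("e1") if r["analyte"] != "potassium"]
        rows.append(event("e1", "potassium", 3.0, hours=-4))
        rows.append(event("e1", "potassium", 9.0, hours=4))
        enc, _ = assemble_encounters(pd.DataFrame(rows))
        assert enc[0].panel[PANEL_ANALYTES.index("potassium")] == 3.0

    def test_outside_window_excluded(self):
        rows = [r for r in full_encounter("e1") if r["analyte"] != "chloride"]
        rows.append(event("e1", "chloride", 100.0, hours=24 * 8))
        enc, audit = assemble_encounters(pd.DataFrame(rows), window_days=7.0)
        assert enc == [] and audit.iloc[0]["reason"] == "incomplete_panel"

    def test_max_ammonia_selected_not_first(self):
        rows = full_encounter("e1", ammonia=60.0)
        rows.append(event("e1", AMMONIA, 120.0, hours=5))
        enc, _ = assemble_encounters(pd.DataFrame(rows))
        assert enc[0].max_ammonia == 120.0

    def test_multiple_encounters_per_patient(self):
        rows = full_encounter("e1", pid="p9") + full_encounter("e2", pid="p9", hours_offset=100)
        enc, _ = assemble_encounters(pd.DataFrame(rows))
        assert {e.encounter_id for e in enc} == {"e1", "e2"}

    def test_unknown_analyte_rejected(self):
        ev = pd.DataFrame([event("e1", AMMONIA, 80.0), event("e1", "glucose", 5.0)])
        with pytest.raises(ValueError, match="glucose"):
            assemble_encounters(ev)

    def test_unparseable_timestamp_rejected(self):
        ev = pd.DataFrame(full_encounter("e1")).astype({"timestamp": str})
        ev.loc[0, "timestamp"] = "not a time"
        with pytest.raises(ValueError, match="timestamp"):
            assemble_encounters(ev)


class TestScaling:
    def test_closed_form_column(self):
        x = np.array([[1.0], [2.0], [3.0]])
        z = scale_matrix(x)
        assert z[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871], abs=1e-8)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4))
        z = scale_matrix(x)
        assert np.allclose(scale_matrix(z), z, atol=1e-9)

    def test_columns_centered_unit_variance(self):
        rng = np.random.default_rng(1)
        z = scale_matrix(rng.normal(5, 3, size=(100, 11)))
        assert np.all(np.abs(z.mean(axis=0)) < 1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0)

    def test_constant_column_names_analyte(self):
        x = np.ones((5, 2))
        x[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="sodium"):
            scale_matrix(x, names=["potassium", "sodium"])


class TestGraph:
    def test_line_of_three_k1(self):
        x = np.array([[0.0], [1.0], [3.0]])
        g = build_graph(x, ClusterConfig(n_neighbors=1, n_pcs=1))
        assert set(map(tuple, g.get_edgelist())) == {(0, 1), (1, 2)}

    def test_minkowski_p2_matches_euclidean_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 11))
        g = build_graph(x, ClusterConfig(n_neighbors=3, minkowski_p=2.0))
        d = squareform(pdist(x))
        np.fill_diagonal(d, np.inf)
        for i in range(30):
            nbrs = set(np.argsort(d[i])[:3])
            edges = {j for a, j in g.get_edgelist() if a == i} | {
                a for a, j in g.get_edgelist() if j == i
            }
            assert nbrs <= edges  # union-symmetrization may add more

    def test_pca_full_rank_preserves_distances(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 11))
        from sklearn.decomposition import PCA

        y = PCA(n_components=11, svd_solver="full").fit_transform(x)
        assert np.allclose(pdist(x), pdist(y), atol=1e-8)

    def test_no_self_edges_and_symmetric(self):
        rng = np.random.default_rng(4)
        g = build_graph(rng.normal(size=(25, 5)), ClusterConfig(n_neighbors=4, n_pcs=5))
        assert all(a != b for a, b in g.get_edgelist())
        assert not g.is_directed()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            build_graph(np.zeros((4, 2)), ClusterConfig(n_neighbors=5))


class TestLeiden:
    def test_two_cliques_two_clusters(self):
        import igraph as ig

        g = ig.Graph.Full(5) + ig.Graph.Full(5)  # disjoint union
        res = cluster_graph(g, resolution=0.2, seed=0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        g = build_graph(rng.normal(size=(60, 11)), ClusterConfig())
        a = cluster_graph(g, 0.2, seed=3)
        b = cluster_graph(g, 0.2, seed=3)
        assert (a.labels == b.labels).all()

    def test_labels_ordered_by_size(self):
        import igraph as ig

        g = ig.Graph.Full(8) + ig.Graph.Full(3)
        res = cluster_graph(g, 0.2, seed=0)
        assert (res.labels[:8] == 0).all() and (res.labels[8:] == 1).all()

    def test_empty_graph_rejected(self):
        import igraph as ig

        with pytest.raises(ValueError):
            cluster_graph(ig.Graph(), 0.2, 0)


@pytest.fixture(scope="module")
def planted():
    enc, truth, _ = generate_lab_encounters(separated_lab_params(n=400, seed=42))
    return enc, truth


class TestRecovery:
    def test_planted_clusters_recovered(self, planted):
        enc, truth = planted
        res = cluster_encounters(enc, ClusterConfig(n_neighbors=5, resolution=0.2, seed=0))
        assert res.n_clusters == 4
        assert adjusted_rand_score(truth, res.labels) >= 0.99

    @pytest.mark.parametrize("resolution", [0.1, 0.2, 0.3, 0.5])
    def test_recovery_across_resolutions(self, planted, resolution):
        enc, truth = planted
        res = cluster_encounters(enc, ClusterConfig(resolution=resolution, seed=0))
        assert res.n_clusters == 4

    def test_permutation_invariance(self, planted):
        enc, truth = planted
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(enc))
        res0 = cluster_encounters(enc, ClusterConfig(seed=0))
        res1 = cluster_encounters([enc[i] for i in perm], ClusterConfig(seed=0))
        assert adjusted_rand_score(res0.labels[perm], res1.labels) == 1.0

    def test_kmeans_baseline_agrees(self, planted):
        enc, truth = planted
        mat, names = encounter_matrix(enc)
        labels = kmeans_baseline(scale_matrix(mat, names), 4, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.99

    def test_nearest_center_oracle_agrees(self, planted):
        """Pipeline partition matches assignment to the nearest true center."""
        enc, truth = planted
        mat, _ = encounter_matrix(enc)
        centers = np.stack([mat[truth == k].mean(axis=0) for k in range(4)])
        oracle = np.argmin(
            ((mat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        res = cluster_encounters(enc, ClusterConfig(seed=0))
        assert adjusted_rand_score(oracle, res.labels) >= 0.99


class TestProfiles:
    def test_single_cluster_equals_global_median(self):
        enc, _, _ = generate_lab_encounters(separated_lab_params(n_clusters=1, n=30, seed=1))
        mat, names = encounter_matrix(enc)
        prof = cluster_profiles(enc, np.zeros(30, dtype=int))
        for j, a in enumerate(names):
            cell = prof[(prof["cluster"] == 0) & (prof["analyte"] == a)]["median"].iloc[0]
            assert cell == pytest.approx(np.median(mat[:, j]))

    def test_singleton_cluster_is_its_own_median(self):
        enc, _, _ = generate_lab_encounters(separated_lab_params(n_clusters=1, n=5, seed=2))
        labels = [0, 0, 0, 0, 1]
        prof = cluster_profiles(enc, labels)
        for j, a in enumerate(PANEL_ANALYTES):
            cell = prof[(prof["cluster"] == 1) & (prof["analyte"] == a)]["median"].iloc[0]
            assert cell == pytest.approx(enc[4].panel[j])

    def test_random_split_matches_brute_force(self):
        enc, _, _ = generate_lab_encounters(separated_lab_params(n_clusters=2, n=40, seed=3))
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=40)
        mat, names = encounter_matrix(enc)
        prof = cluster_profiles(enc, labels)
        for k in (0, 1):
            for j, a in enumerate(names):
                cell = prof[(prof["cluster"] == k) & (prof["analyte"] == a)]
                assert cell["median"].iloc[0] == pytest.approx(np.median(mat[labels == k, j]))

    def test_misaligned_labels_rejected(self):
        enc, _, _ = generate_lab_encounters(separated_lab_params(n_clusters=1, n=5, seed=4))
        with pytest.raises(ValueError):
            cluster_profiles(enc, [0, 1])


def test_end_to_end_determinism():
    enc, _, _ = generate_lab_encounters(separated_lab_params(n=120, seed=9))
    events = lab_events_frame(enc, seed=10)
    a_enc, _ = assemble_encounters(events)
    b_enc, _ = assemble_encounters(events)
    a = cluster_encounters(a_enc, ClusterConfig(seed=5))
    b = cluster_encounters(b_enc, ClusterConfig(seed=5))
    assert (a.labels == b.labels).all()
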