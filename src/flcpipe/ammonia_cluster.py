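"""Hyperammonemia encounter assembly and graph-based clustering.

Encounters where the maximum blood ammonia reaches a threshold (default
50 µmol/L) are assembled into a complete 11-analyte metabolic-panel matrix:
for each analyte the measurement temporally closest to the max-ammonia draw
is taken, and encounters missing any analyte within a seven-day window are
excluded.  The matrix is z-scored, reduced by PCA, turned into a k-nearest-
neighbor graph under a Minkowski metric, and partitioned with Leiden
community detection — the same workflow used for cell-type identification in
single-cell transcriptomics, applied to routine clinical chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

AMMONIA = "ammonia"

#: The 11 analytes forming the clustering feature space: the encounter's
#: maximum ammonia plus the 10 complete-metabolic-panel analytes matched to it.
PANEL_ANALYTES = (
    "ammonia",
    "sodium",
    "potassium",
    "chloride",
    "bicarbonate",
    "BUN",
    "creatinine",
    "ALT",
    "AST",
    "total_bilirubin",
    "alkaline_phosphatase",
)

#: Valid names in a lab-event stream.
ANALYTE_VOCABULARY = frozenset(PANEL_ANALYTES)

N_PANEL = len(PANEL_ANALYTES)


@dataclass(frozen=True)
class LabEncounter:
    """One hyperammonemia encounter: max ammonia + 11 matched panel values."""

    encounter_id: str
    patient_id: str
    diagnosis_group: str
    max_ammonia: float
    panel: tuple[float, ...]
    panel_times: tuple[pd.Timestamp, ...] = ()

    def __post_init__(self) -> None:
        if len(self.panel) != N_PANEL:
            raise ValueError(f"panel must have {N_PANEL} values, got {len(self.panel)}")


@dataclass(frozen=True)
class ClusterConfig:
    """Neighborhood-graph and Leiden parameters.

    ``n_pcs`` is capped at min(n_pcs, n_features, n-1); with 11 analytes a
    nominal 40 principal components reduces to at most 11 (a full-rank
    rotation that preserves Euclidean geometry exactly).
    """

    n_neighbors: int = 5
    n_pcs: int = 40
    minkowski_p: float = 2.0
    resolution: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.minkowski_p < 1:
            raise ValueError("minkowski_p must be >= 1")


@dataclass(frozen=True)
class ClusterResult:
    encounter_ids: tuple[str, ...]
    labels: np.ndarray
    n_clusters: int
    config: ClusterConfig
    embedding_2d: Optional[np.ndarray] = field(default=None, compare=False)


def assemble_encounters(
    events: pd.DataFrame,
    ammonia_threshold: float = 50.0,
    window_days: float = 7.0,
) -> tuple[list[LabEncounter], pd.DataFrame]:
    """Assemble complete-panel hyperammonemia encounters from a lab-event stream.

    ``events`` columns: patient_id, encounter_id, analyte, value, timestamp
    (ISO-8601 or datetime), optionally diagnosis.  Per encounter the maximum
    ammonia is located (earliest draw wins a tie); encounters below the
    threshold are dropped, and for retained ones each panel analyte takes its
    measurement nearest in absolute time to the max-ammonia draw (earlier
    wins an exact tie).  Encounters missing any analyte within the window are
    excluded.  Returns encounters plus an audit table of exclusions.
    """
    ev = events.copy()
    unknown = set(ev["analyte"].unique()) - ANALYTE_VOCABULARY
    if unknown:
        raise ValueError(f"unknown analyte name(s): {sorted(unknown)}")
    with pd.option_context("mode.chained_assignment", None):
        ts = pd.to_datetime(ev["timestamp"], errors="coerce", format="mixed")
    if ts.isna().any():
        bad = ev.loc[ts.isna(), "timestamp"].iloc[0]
        raise ValueError(f"unparseable timestamp: {bad!r}")
    ev["timestamp"] = ts

    window = pd.Timedelta(days=window_days)
    panel_names = [a for a in PANEL_ANALYTES if a != AMMONIA]
    encounters: list[LabEncounter] = []
    audit_rows: list[dict] = []

    for enc_id, grp in ev.groupby("encounter_id", sort=True):
        ammonia = grp[grp["analyte"] == AMMONIA]
        if ammonia.empty:
            audit_rows.append({"encounter_id": enc_id, "reason": "no_ammonia"})
            continue
        amax = ammonia["value"].max()
        if amax < ammonia_threshold:
            audit_rows.append({"encounter_id": enc_id, "reason": "below_threshold"})
            continue
        peak = ammonia[ammonia["value"] == amax].sort_values("timestamp").iloc[0]
        t0 = peak["timestamp"]

        values: dict[str, float] = {AMMONIA: float(amax)}
        times: dict[str, pd.Timestamp] = {AMMONIA: t0}
        complete = True
        for analyte in panel_names:
            cand = grp[grp["analyte"] == analyte].copy()
            if not cand.empty:
                cand["absdt"] = (cand["timestamp"] - t0).abs()
                cand = cand[cand["absdt"] <= window]
            if cand.empty:
                complete = False
                break
            # nearest in absolute time; on an exact tie the earlier draw wins
            cand = cand.sort_values(["absdt", "timestamp"], kind="stable")
            best = cand.iloc[0]
            values[analyte] = float(best["value"])
            times[analyte] = best["timestamp"]
        if not complete:
            audit_rows.append({"encounter_id": enc_id, "reason": "incomplete_panel"})
            continue

        diagnosis = (
            str(grp["diagnosis"].iloc[0]) if "diagnosis" in grp.columns else "UNKNOWN"
        )
        encounters.append(
            LabEncounter(
                encounter_id=str(enc_id),
                patient_id=str(grp["patient_id"].iloc[0]),
                diagnosis_group=diagnosis,
                max_ammonia=float(amax),
                panel=tuple(values[a] for a in PANEL_ANALYTES),
                panel_times=tuple(times[a] for a in PANEL_ANALYTES),
            )
        )

    audit = pd.DataFrame(audit_rows, columns=["encounter_id", "reason"])
    return encounters, audit


def encounter_matrix(
    encounters: Sequence[LabEncounter], include_ammonia: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Stack encounters into an n x 11 feature matrix (n x 10 without ammonia)."""
    names = list(PANEL_ANALYTES)
    mat = np.asarray([e.panel for e in encounters], dtype=float)
    if not include_ammonia:
        keep = [i for i, a in enumerate(names) if a != AMMONIA]
        mat = mat[:, keep]
        names = [names[i] for i in keep]
    return mat, names


def scale_matrix(
    matrix: np.ndarray, names: Optional[Sequence[str]] = None, ddof: int = 0
) -> np.ndarray:
    """Z-score each column to mean 0 and unit variance (population SD, ddof=0).

    Raises on constant columns, naming the offending analyte.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        which = names[zero[0]] if names is not None else f"column {zero[0]}"
        raise ValueError(f"zero-variance analyte: {which}")
    return (x - mu) / sd


def build_graph(matrix: np.ndarray, config: ClusterConfig = ClusterConfig()) -> ig.Graph:
    """k-nearest-neighbor graph under a Minkowski-p metric after optional PCA.

    PCA keeps min(n_pcs, n_features, n-1) components.  The directed kNN
    relation is union-symmetrized into an undirected simple graph with no
    self-edges.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if n <= config.n_neighbors:
        raise ValueError(f"need more than n_neighbors={config.n_neighbors} points, got {n}")
    n_pcs = min(config.n_pcs, x.shape[1], n - 1)
    x = PCA(n_components=n_pcs, svd_solver="full", random_state=config.seed).fit_transform(x)
    nn = NearestNeighbors(
        n_neighbors=config.n_neighbors + 1, metric="minkowski", p=config.minkowski_p
    ).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 0.2, seed: int = 0) -> ClusterResult:
    """Leiden community detection (RB-modularity objective) on a kNN graph.

    Labels are relabeled by descending cluster size (ties broken by first
    occurrence) and are deterministic given the seed.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    labels = _relabel_by_size(raw)
    return ClusterResult(
        encounter_ids=tuple(str(i) for i in range(graph.vcount())),
        labels=labels,
        n_clusters=int(labels.max()) + 1,
        config=ClusterConfig(resolution=resolution, seed=seed),
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    # descending size, ties by ascending original id
    order = sorted(range(len(ids)), key=lambda k: (-counts[k], ids[k]))
    mapping = {int(ids[k]): rank for rank, k in enumerate(order)}
    return np.asarray([mapping[int(l)] for l in labels], dtype=int)


def cluster_encounters(
    encounters: Sequence[LabEncounter],
    config: ClusterConfig = ClusterConfig(),
    include_ammonia: bool = True,
) -> ClusterResult:
    """Full scale → PCA → kNN → Leiden pipeline over assembled encounters.

    The default feature matrix is the full 11-variable panel (max ammonia +
    10 CMP analytes); ``include_ammonia=False`` drops ammonia to probe how
    much structure the selection variable itself contributes.
    """
    mat, names = encounter_matrix(encounters, include_ammonia=include_ammonia)
    scaled = scale_matrix(mat, names)
    graph = build_graph(scaled, config)
    res = cluster_graph(graph, resolution=config.resolution, seed=config.seed)
    return ClusterResult(
        encounter_ids=tuple(e.encounter_id for e in encounters),
        labels=res.labels,
        n_clusters=res.n_clusters,
        config=config,
    )


def kmeans_baseline(matrix: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """K-means labels on a scaled matrix, as a comparison baseline."""
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return _relabel_by_size(km.fit_predict(matrix))


def cluster_profiles(
    encounters: Sequence[LabEncounter], labels: Sequence[int]
) -> pd.DataFrame:
    """Per-cluster, per-analyte median and quartiles on raw (unscaled) values."""
    if len(encounters) != len(labels):
        raise ValueError("labels must align with encounters")
    mat, names = encounter_matrix(encounters)
    df = pd.DataFrame(mat, columns=names)
    df["cluster"] = np.asarray(labels, dtype=int)
    long = df.melt(id_vars="cluster", var_name="analyte", value_name="value")
    prof = (
        long.groupby(["cluster", "analyte"], sort=True)["value"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
        .reset_index()
    )
    return prof


def encounters_frame(encounters: Sequence[LabEncounter], labels=None) -> pd.DataFrame:
    """One row per encounter: ids, diagnosis, max ammonia, the 11 analytes."""
    mat, names = encounter_matrix(encounters)
    df = pd.DataFrame(mat, columns=names)
    df.insert(0, "encounter_id", [e.encounter_id for e in encounters])
    df.insert(1, "patient_id", [e.patient_id for e in encounters])
    df.insert(2, "diagnosis", [e.diagnosis_group for e in encounters])
    df.insert(3, "max_ammonia", [e.max_ammonia for e in encounters])
    if labels is not None:
        df["cluster"] = np.asarray(labels, dtype=int)
    return df


def umap_embedding(matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """Optional 2-D UMAP embedding for visualization; no result depends on it."""
    import umap

    return umap.UMAP(n_components=2, random_state=seed).fit_transform(matrix)
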