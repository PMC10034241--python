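"""Cluster hyperammonemia encounters by their metabolic-panel signature.

Simulates a lab-event stream from four biochemical archetypes, reassembles
complete-panel encounters (max ammonia >= 50, all analytes within 7 days),
and partitions the z-scored 11-analyte matrix with a kNN graph + Leiden.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from flcpipe import ClusterConfig, assemble_encounters, cluster_encounters, cluster_profiles
from flcpipe.simulate import LabSimParams, generate_lab_encounters, lab_events_frame

centers = np.full((4, 11), 100.0)
for i in range(4):
    centers[i, i] += 10.0  # 10-SD separation on one analyte each

params = LabSimParams(
    n_clusters=4,
    cluster_centers=centers,
    cluster_scales=np.ones((4, 11)),
    cluster_weights=[0.25] * 4,
    n_encounters=400,
    seed=42,
)
encounters, truth, _ = generate_lab_encounters(params)
events = lab_events_frame(encounters, seed=43)
print(f"lab-event stream: {len(events)} rows")

assembled, audit = assemble_encounters(events, ammonia_threshold=50.0, window_days=7.0)
print(f"complete-panel encounters retained: {len(assembled)} (excluded: {len(audit)})")

res = cluster_encounters(assembled, ClusterConfig(n_neighbors=5, resolution=0.2, seed=0))
ari = adjusted_rand_score(truth, res.labels)
print(f"Leiden clusters found: {res.n_clusters}")
print(f"adjusted Rand index vs planted truth: {ari:.3f}")

prof = cluster_profiles(assembled, res.labels)
print("\nper-cluster ammonia medians:")
print(prof[prof["analyte"] == "ammonia"][["cluster", "q1", "median", "q3"]].to_string(index=False))
# ARI 1.0 means the graph partition exactly recovers the planted mixture;
# the profile table is the numeric backbone of a violin-plot figure.
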