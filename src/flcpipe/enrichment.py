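"""Diagnosis-enrichment testing within clusters of hyperammonemia encounters.

For each diagnosis group and each cluster (or pooled pair of clusters) a
2x2 contingency table — in-cluster vs. out, diagnosis vs. other — is tested
with Fisher's exact test.  Multiple testing is handled the way the source
analysis did: single-cluster p-values are multiplied by the number of
clusters, and two-cluster p-values by C(k, 2), capped at 1.  That is a
Bonferroni-style family-wise correction even though the analysis labeled it
"FDR"; a genuine Benjamini–Hochberg option is provided and clearly
distinguished.  Encounters, not unique patients, are the unit of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = in-cluster & diagnosis, b = in-cluster & other,
    c = out-cluster & diagnosis, d = out-cluster & other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    diagnosis: str
    clusters: frozenset[int]
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    p_adjusted: float
    correction_factor: float


def make_table(
    labels: Sequence[int],
    diagnosis_flags: Sequence[bool],
    cluster_set: Iterable[int],
) -> ContingencyTable2x2:
    """Cross-tabulate cluster membership against a diagnosis flag.

    ``cluster_set`` of size two pools both clusters as the "in" group.
    """
    labels = np.asarray(labels, dtype=int)
    flags = np.asarray(diagnosis_flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and diagnosis_flags must align")
    cset = set(int(c) for c in cluster_set)
    if not cset:
        raise ValueError("cluster_set must be non-empty")
    unknown = cset - set(np.unique(labels).tolist())
    if unknown:
        raise ValueError(f"unknown cluster label(s): {sorted(unknown)}")
    inside = np.isin(labels, list(cset))
    a = int(np.sum(inside & flags))
    b = int(np.sum(inside & ~flags))
    c = int(np.sum(~inside & flags))
    d = int(np.sum(~inside & ~flags))
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p-value.

    The two-sided p sums the probabilities of all tables (under the
    conditional hypergeometric null) no more likely than the observed one.
    The odds ratio is ad/bc: infinite when bc = 0 with ad > 0, zero when
    ad = 0 with bc > 0, and NaN when both vanish.
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(odds), float(p)


def adjust_single(p_values: Sequence[float], n_clusters: int) -> list[float]:
    """Multiply each p by the number of clusters, capped at 1."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    return [min(1.0, p * n_clusters) for p in p_values]


def pair_correction_factor(n_clusters: int, literal_factor: Optional[int] = None) -> int:
    """C(n_clusters, 2), or an explicit literal override."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2 for pair analysis")
    return literal_factor if literal_factor is not None else comb(n_clusters, 2)


def adjust_pairs(
    p_values: Sequence[float], n_clusters: int, literal_factor: Optional[int] = None
) -> list[float]:
    """Multiply each p by C(n_clusters, 2) (or a literal override), capped at 1."""
    factor = pair_correction_factor(n_clusters, literal_factor)
    return [min(1.0, p * factor) for p in p_values]


def enrich_all(
    labels: Sequence[int],
    diagnoses: Sequence[str],
    include_pairs: bool = False,
    method: str = "multiplicative",
    background: Optional[str] = None,
    pair_literal_factor: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Test every diagnosis against every cluster (and cluster pair).

    ``diagnoses`` gives one group label per encounter; entries equal to
    ``background`` (or empty/None) are never tested as a diagnosis but count
    in the margins.  ``method='multiplicative'`` applies the x-k / x-C(k,2) correction
    (x k for singles, x C(k,2) for pairs); ``method='bh'`` applies
    Benjamini–Hochberg separately within the single and pair families.
    Results are sorted by adjusted then raw p-value.
    """
    if method not in ("multiplicative", "bh"):
        raise ValueError("method must be 'multiplicative' or 'bh'")
    labels = np.asarray(labels, dtype=int)
    diag = ["" if d is None else str(d) for d in diagnoses]
    if len(diag) != len(labels):
        raise ValueError("diagnoses must align with labels")
    tested = sorted(
        {d for d in diag if d and d != "UNKNOWN" and (background is None or d != background)}
    )
    if not tested:
        return []
    clusters = sorted(int(c) for c in np.unique(labels))
    k = len(clusters)
    if include_pairs and k < 2:
        raise ValueError("pair analysis requires >= 2 clusters")

    units: list[tuple[str, frozenset[int]]] = [
        (d, frozenset({c})) for d in tested for c in clusters
    ]
    if include_pairs:
        units += [
            (d, frozenset(pair)) for d in tested for pair in combinations(clusters, 2)
        ]

    rows = []
    for d, cset in units:
        flags = [x == d for x in diag]
        table = make_table(labels, flags, cset)
        odds, p = fisher_exact(table)
        rows.append((d, cset, table, odds, p))

    singles = [i for i, r in enumerate(rows) if len(r[1]) == 1]
    pairs = [i for i, r in enumerate(rows) if len(r[1]) == 2]
    adjusted = np.empty(len(rows))
    factor = np.empty(len(rows))
    if method == "multiplicative":
        pf = pair_correction_factor(k, pair_literal_factor) if pairs else 0
        for i in singles:
            adjusted[i] = min(1.0, rows[i][4] * k)
            factor[i] = k
        for i in pairs:
            adjusted[i] = min(1.0, rows[i][4] * pf)
            factor[i] = pf
    else:
        for family in (singles, pairs):
            if family:
                ps = [rows[i][4] for i in family]
                adj = multipletests(ps, method="fdr_bh")[1]
                for i, a in zip(family, adj):
                    adjusted[i] = a
                    factor[i] = float("nan")

    results = [
        EnrichmentResult(
            diagnosis=d,
            clusters=cset,
            table=table,
            odds_ratio=odds,
            p_value=p,
            p_adjusted=float(adjusted[i]),
            correction_factor=float(factor[i]),
        )
        for i, (d, cset, table, odds, p) in enumerate(rows)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.diagnosis, sorted(r.clusters)))
    return results
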