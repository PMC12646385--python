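"""Cluster-based distributional fidelity, scaled to [0, 1].

Real and synthetic records are pooled, encoded, and clustered; in each
cluster the fraction of real records is compared with the overall real
fraction c.  With cluster-size weights w_j = n_j / n the purity statistic

    U = sum_j w_j (p_j - c)^2

has maximum c(1-c), attained when every cluster is purely real or purely
synthetic, and minimum 0 when real and synthetic records are perfectly
mixed.  The reported score is 1 - U / (c(1-c)), so 1 = maximum fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import Cohort
from .generators import SyntheticEnsemble

__all__ = [
    "ClusterFidelityResult",
    "purity_statistic",
    "encode_for_clustering",
    "cluster_fidelity",
    "ensemble_fidelity",
]


@dataclass
class ClusterFidelityResult:
    score: float
    n_clusters: int
    U: float
    real_fraction: float


def purity_statistic(labels: np.ndarray, is_real: np.ndarray) -> ClusterFidelityResult:
    """Compute U and the scaled score from cluster labels and real flags."""
    labels = np.asarray(labels)
    is_real = np.asarray(is_real, dtype=bool)
    n = labels.size
    c = is_real.mean()
    if c <= 0 or c >= 1:
        raise ValueError("both real and synthetic records are required")
    U = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        mask = labels == g
        w = mask.mean()
        p = is_real[mask].mean()
        U += w * (p - c) ** 2
    score = 1.0 - U / (c * (1.0 - c))
    return ClusterFidelityResult(
        score=float(score), n_clusters=int(uniq.size), U=float(U), real_fraction=float(c)
    )


def encode_for_clustering(real: pd.DataFrame, synthetic: pd.DataFrame, meta) -> np.ndarray:
    """Pool rows and encode for k-means.

    Categoricals are one-hot (missing as its own indicator); continuous
    columns are standardised by the pooled mean/sd, missing values mean-
    filled with a companion missingness indicator.
    """
    pooled = pd.concat([real, synthetic], axis=0, ignore_index=True)
    blocks: list[np.ndarray] = []
    for m in meta:
        col = pooled[m.name]
        if m.vtype == "categorical":
            s = col.astype(object).where(col.notna(), "__missing__").astype(str)
            levels = sorted(s.unique())
            for lv in levels:
                blocks.append((s == lv).to_numpy(dtype=float))
        else:
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            miss = np.isnan(v)
            mu = np.nanmean(v) if not miss.all() else 0.0
            sd = np.nanstd(v) if not miss.all() else 1.0
            sd = sd if sd > 0 else 1.0
            blocks.append(np.where(miss, 0.0, (v - mu) / sd))
            if miss.any():
                blocks.append(miss.astype(float))
    return np.column_stack(blocks)


def cluster_fidelity(
    real: Cohort, synthetic: Cohort, G: int = 20, seed: int = 0
) -> ClusterFidelityResult:
    """Cluster-based fidelity of one synthetic cohort against a real one.

    Both cohorts must share a schema; fidelity is conventionally evaluated
    on the core projection (done by the caller / pipeline).  k-means uses a
    fixed seed and 10 restarts so the reported score is deterministic.
    """
    if [m.name for m in real.meta] != [m.name for m in synthetic.meta]:
        raise ValueError("real and synthetic cohorts must share a schema")
    n_pool = real.n + synthetic.n
    if G < 2:
        raise ValueError("G must be at least 2")
    if G > n_pool:
        raise ValueError("G exceeds the pooled number of records")
    X = encode_for_clustering(real.records, synthetic.records, real.meta)
    # fit on lexicographically sorted rows so the clustering depends only on
    # the pooled multiset of records, making the score invariant to swapping
    # the real/synthetic arguments when sizes are equal
    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=G, n_init=10, random_state=seed)
    km.fit(X[order])
    labels = km.predict(X)
    is_real = np.zeros(n_pool, dtype=bool)
    is_real[: real.n] = True
    res = purity_statistic(labels, is_real)
    return ClusterFidelityResult(
        score=res.score, n_clusters=G, U=res.U, real_fraction=res.real_fraction
    )


def ensemble_fidelity(
    real: Cohort, ensemble: SyntheticEnsemble, G: int = 20, seed: int = 0
) -> tuple[float, list[float]]:
    """Mean fidelity score over the replicates of an ensemble."""
    scores = [
        cluster_fidelity(real, rep, G=G, seed=seed).score for rep in ensemble.replicates
    ]
    return float(np.mean(scores)), scores
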