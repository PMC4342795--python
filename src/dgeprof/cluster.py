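"""Time-course clustering of DE gene profiles and trajectory typing.

Profiles are log2(TPM + floor), optionally row-standardized.  K-means uses
a seeded k-means++ initialization with deterministic Lloyd iterations;
empty clusters are re-seeded from the point farthest from its center.
Clusters whose mean profile trends down across the course are labelled
``type_I``, upward trends ``type_II``, anything else (e.g. peak shapes)
``complex``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .de import DegSet
from .mapping import ExpressionMatrix

TYPE_DOWN = "type_I"
TYPE_UP = "type_II"
TYPE_COMPLEX = "complex"


@dataclass
class ProfileMatrix:
    values: pd.DataFrame  # genes x time points
    transform: str

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster id, 1-based
    means: pd.DataFrame  # cluster id x time points (profile space)
    k: int
    seed: int
    types: dict[int, str] = field(default_factory=dict)

    def gene_types(self) -> pd.Series:
        if not self.types:
            raise ValueError("cluster types not classified yet")
        return self.labels.map(self.types)


def build_profiles(
    matrix: ExpressionMatrix,
    degs: DegSet | list[str],
    transform: str = "zscore",
    floor: float = 1.0,
) -> ProfileMatrix:
    """log2(TPM + floor) rows for the DEG set; ``zscore`` standardizes rows.

    Constant rows z-score to all zeros rather than dividing by zero.
    """
    if matrix.tpm is None:
        raise ValueError("matrix has no TPM view; run normalize_tpm first")
    genes = sorted(degs.genes) if isinstance(degs, DegSet) else list(degs)
    missing = [g for g in genes if g not in matrix.tpm.index]
    if missing:
        raise ValueError(f"DEG genes absent from matrix: {missing[:10]}")
    values = np.log2(matrix.tpm.loc[genes] + floor)
    if transform == "zscore":
        arr = values.to_numpy()
        mean = arr.mean(axis=1, keepdims=True)
        std = arr.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        values = pd.DataFrame(
            (arr - mean) / std, index=values.index, columns=values.columns
        )
    elif transform != "log":
        raise ValueError(f"unknown transform {transform!r}")
    return ProfileMatrix(values=values, transform=transform)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[i] = x[rng.integers(n)]
            continue
        probs = d2 / total
        centers[i] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centers[i]) ** 2, axis=1))
    return centers


def kmeans_cluster(
    profiles: ProfileMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Deterministic seeded k-means with Euclidean distance.

    Final cluster ids are relabelled 1..k by descending early-timepoint
    mean so that down-trending clusters come first.
    """
    x = profiles.values.to_numpy(dtype=float)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, k, rng)
    assign = np.full(n, -1)
    for _ in range(max_iter):
        dist = cdist(x, centers)
        new_assign = dist.argmin(axis=1)
        # re-seed empty clusters from the globally farthest point
        for c in range(k):
            if not np.any(new_assign == c):
                far = dist[np.arange(n), new_assign].argmax()
                centers[c] = x[far]
                new_assign[far] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = x[assign == c]
            if len(members):
                centers[c] = members.mean(axis=0)

    means = np.vstack([x[assign == c].mean(axis=0) for c in range(k)])
    early = means[:, : max(1, min(2, means.shape[1]))].mean(axis=1)
    order = np.argsort(-early, kind="mergesort")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(c)] for c in assign], index=profiles.values.index, name="cluster"
    )
    means_df = pd.DataFrame(
        means[order],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=profiles.values.columns,
    )
    return ClusterAssignment(labels=labels, means=means_df, k=k, seed=seed)


def hierarchical_cluster(
    profiles: ProfileMatrix, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative tree (scipy linkage matrix) and deterministic leaf order."""
    if len(profiles.genes) < 2:
        raise ValueError("hierarchical clustering needs at least 2 genes")
    z = linkage(profiles.values.to_numpy(dtype=float), method=method, metric="euclidean")
    order = [profiles.genes[i] for i in leaves_list(z)]
    return z, order


def classify_cluster_types(
    assignment: ClusterAssignment,
    min_change: float = 1.0,
    trend_cutoff: float = 0.5,
) -> ClusterAssignment:
    """Label each cluster type_I / type_II / complex from its mean profile.

    type_I: early-phase mean (first two points) exceeds late-phase mean
    (last two) by >= ``min_change`` in profile units AND the Spearman trend
    of the mean profile against time is <= -``trend_cutoff``.  type_II is
    symmetric upward; everything else is complex.
    """
    types: dict[int, str] = {}
    for cluster, profile in assignment.means.iterrows():
        vec = profile.to_numpy(dtype=float)
        early = vec[:2].mean()
        late = vec[-2:].mean()
        if np.allclose(vec, vec[0]):
            rho = 0.0
        else:
            rho = float(spearmanr(np.arange(len(vec)), vec).statistic)
        if early - late >= min_change and rho <= -trend_cutoff:
            types[int(cluster)] = TYPE_DOWN
        elif late - early >= min_change and rho >= trend_cutoff:
            types[int(cluster)] = TYPE_UP
        else:
            types[int(cluster)] = TYPE_COMPLEX
    assignment.types = types
    return assignment


def within_cluster_ss(profiles: ProfileMatrix, assignment: ClusterAssignment) -> float:
    """K-means objective of an assignment (used by invariance tests)."""
    x = profiles.values.to_numpy(dtype=float)
    total = 0.0
    for c in range(1, assignment.k + 1):
        members = x[(assignment.labels == c).to_numpy()]
        if len(members):
            total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total
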