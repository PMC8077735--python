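"""Class balancing by SMOTE oversampling plus K-means
similarity-based undersampling (SMOTE-KSU).

The balance target N is computed from the class counts as

    N = round[ k1 * n0  -  k0 * n1 ],      k0 = k1 = 0.5 by default,

with rounding half away from zero, and both classes are driven to the
common size M = n1 + N: the minority (positive) class gains
``additions = M - n1`` SMOTE interpolants, the majority (negative)
class loses ``removals = n0 - M`` members chosen by KSU.

KSU clusters the majority class with k-means (k = 6 by default),
rescales each feature column of a cluster by its column maximum,
ranks within-cluster sample pairs by the scaled squared-Euclidean
dissimilarity

    D1[p, q] = (1/n) * || pi_p - pi_q ||^2        (n = cluster size),

and then walks the globally merged, ascending-sorted pair list deleting
one randomly chosen member of each still-intact most-similar pair until
the removal quota is met.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# The balance plan
# ---------------------------------------------------------------------------

def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, with halves moving away from zero
    (so 11322.5 -> 11323), unlike Python's banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ResamplePlan:
    """Sizes that balance a (n1 positive, n0 negative) dataset."""

    n1: int
    n0: int
    k0: float = 0.5
    k1: float = 0.5
    N: int = field(init=False)
    M: int = field(init=False)
    additions: int = field(init=False)
    removals: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.n0 > self.n1 >= 1:
            raise ValueError(
                f"classes already balanced or inverted (n1={self.n1}, n0={self.n0})"
            )
        N = round_half_away_from_zero(self.k1 * self.n0 - self.k0 * self.n1)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "M", self.n1 + N)
        object.__setattr__(self, "additions", self.M - self.n1)
        object.__setattr__(self, "removals", self.n0 - self.M)


def compute_plan(n1: int, n0: int, k0: float = 0.5, k1: float = 0.5) -> ResamplePlan:
    """Compute the balance target for n1 positives vs n0 negatives."""
    return ResamplePlan(n1=n1, n0=n0, k0=k0, k1=k1)


# ---------------------------------------------------------------------------
# SMOTE oversampling of the minority class
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote(
    minority_matrix: np.ndarray,
    additions: int,
    config: SMOTEConfig,
    return_provenance: bool = False,
):
    """Create exactly `additions` synthetic minority rows.

    Each synthetic row is X + u * (Y - X) for an original row X, one of
    its ``k_neighbors`` nearest minority neighbours Y (Euclidean,
    excluding X itself) and u ~ Uniform(0, 1).  Base rows are cycled
    round-robin over a shuffled copy of the minority set until the quota
    is met, so quotas larger than the minority size are fine.

    With ``return_provenance`` also returns an integer array of
    (base_index, neighbor_index) per synthetic row and the u draws.
    """
    X = np.asarray(minority_matrix, dtype=float)
    n = X.shape[0]
    if additions < 0:
        raise ValueError("additions must be >= 0")
    if additions == 0:
        empty = np.empty((0, X.shape[1]))
        if return_provenance:
            return empty, np.empty((0, 2), dtype=int), np.empty(0)
        return empty
    if n <= config.k_neighbors:
        raise ValueError(
            f"minority class too small ({n}) for k_neighbors={config.k_neighbors}"
        )
    rng = np.random.default_rng(config.seed)
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X)
    # column 0 is the point itself; keep the k true neighbours
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]

    order = rng.permutation(n)
    bases = np.resize(order, additions)  # round-robin over the shuffled set
    picks = rng.integers(0, config.k_neighbors, size=additions)
    u = rng.uniform(0.0, 1.0, size=additions)
    neighbors = neighbor_idx[bases, picks]
    synthetic = X[bases] + u[:, None] * (X[neighbors] - X[bases])
    if return_provenance:
        return synthetic, np.column_stack([bases, neighbors]), u
    return synthetic


# ---------------------------------------------------------------------------
# KSU undersampling of the majority class
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSUConfig:
    n_clusters: int = 6
    seed: int = 0
    kmeans_max_iter: int = 300
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def ksu_dissimilarity(cluster_matrix: np.ndarray) -> list[tuple[int, int, float]]:
    """Within-cluster pair dissimilarities.

    Columns are first divided by their column maximum (a column whose
    maximum is exactly 0 is zeroed); the dissimilarity of rows p < q is
    then ``(1/n) * ||pi_p - pi_q||^2`` with n the cluster size.  Only
    the strict upper triangle is returned, as (p, q, d1) triples in
    row-major pair order.  A single-row cluster yields no pairs.
    """
    A = np.asarray(cluster_matrix, dtype=float)
    n = A.shape[0]
    if n < 2:
        logger.info("cluster of %d row(s): no pairs to rank", n)
        return []
    col_max = A.max(axis=0)
    pi = np.zeros_like(A)
    nonzero = col_max != 0
    pi[:, nonzero] = A[:, nonzero] / col_max[nonzero]
    d1 = pdist(pi, metric="sqeuclidean") / n
    pairs = []
    t = 0
    for p in range(n - 1):
        for q in range(p + 1, n):
            pairs.append((p, q, float(d1[t])))
            t += 1
    return pairs


def ksu_undersample(
    majority_matrix: np.ndarray,
    removals: int,
    config: KSUConfig,
    return_mask: bool = False,
):
    """Remove exactly `removals` majority rows, most-redundant first.

    k-means (k-means++ init, seeded, ``kmeans_restarts`` restarts)
    partitions the rows; all within-cluster pair dissimilarities are
    merged and sorted ascending (ties broken by cluster index then pair
    index, for determinism); walking that list, one member of each pair
    whose two members both still survive is eliminated uniformly at
    random until the quota is met.  If the pair list is exhausted first,
    the remaining quota is drawn uniformly from the survivors, with a
    warning.  Surviving rows are returned in their original order.
    """
    X = np.asarray(majority_matrix, dtype=float)
    n = X.shape[0]
    if removals < 0:
        raise ValueError("removals must be >= 0")
    if removals >= n:
        raise ValueError(f"cannot remove {removals} of {n} rows")
    if removals == 0:
        return (X.copy(), np.ones(n, dtype=bool)) if return_mask else X.copy()
    k = min(config.n_clusters, n)
    rng = np.random.default_rng(config.seed)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=config.kmeans_restarts,
        max_iter=config.kmeans_max_iter,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(X)
    assignments = km.labels_

    ranked: list[tuple[float, int, int, int, int]] = []  # (d1, cluster, pair_no, p, q)
    cluster_sizes = []
    for c in range(k):
        members = np.flatnonzero(assignments == c)
        cluster_sizes.append(len(members))
        for pair_no, (p, q, d1) in enumerate(ksu_dissimilarity(X[members])):
            ranked.append((d1, c, pair_no, int(members[p]), int(members[q])))
    ranked.sort(key=lambda r: (r[0], r[1], r[2]))

    alive = np.ones(n, dtype=bool)
    removed_per_cluster = [0] * k
    quota = removals
    for d1, c, _pair_no, p, q in ranked:
        if quota == 0:
            break
        if alive[p] and alive[q]:
            victim = p if rng.random() < 0.5 else q
            alive[victim] = False
            removed_per_cluster[c] += 1
            quota -= 1
    if quota > 0:
        logger.warning(
            "KSU pair list exhausted; removing remaining %d row(s) uniformly at random",
            quota,
        )
        survivors = np.flatnonzero(alive)
        extra = rng.choice(survivors, size=quota, replace=False)
        alive[extra] = False
    logger.info(
        "KSU removed %d rows (cluster sizes %s, per-cluster removals %s)",
        removals, cluster_sizes, removed_per_cluster,
    )
    return (X[alive], alive) if return_mask else X[alive]


# ---------------------------------------------------------------------------
# The combined resampler
# ---------------------------------------------------------------------------

def smote_ksu(
    feature_matrix: FeatureMatrix,
    plan: ResamplePlan | None = None,
    smote_cfg: SMOTEConfig | None = None,
    ksu_cfg: KSUConfig | None = None,
) -> FeatureMatrix:
    """Balance a labeled feature matrix to M samples per class.

    Positives are the originals plus SMOTE synthetics (flagged in the
    ``synthetic`` mask); negatives are the KSU survivors.  Row order is
    positives (originals, then synthetics) followed by negatives.
    """
    smote_cfg = smote_cfg or SMOTEConfig()
    ksu_cfg = ksu_cfg or KSUConfig()
    n1, n0 = feature_matrix.class_counts()
    if plan is None:
        plan = compute_plan(n1, n0)
    elif (plan.n1, plan.n0) != (n1, n0):
        raise ValueError(
            f"plan was computed for ({plan.n1}, {plan.n0}) but matrix has ({n1}, {n0})"
        )
    pos = feature_matrix.values[feature_matrix.labels == 1]
    neg = feature_matrix.values[feature_matrix.labels == 0]
    synthetic = smote(pos, plan.additions, smote_cfg)
    kept_neg = ksu_undersample(neg, plan.removals, ksu_cfg)
    values = np.vstack([pos, synthetic, kept_neg])
    labels = np.concatenate(
        [np.ones(plan.M, dtype=np.int64), np.zeros(plan.M, dtype=np.int64)]
    )
    synthetic_mask = np.zeros(values.shape[0], dtype=bool)
    synthetic_mask[len(pos) : len(pos) + len(synthetic)] = True
    return FeatureMatrix(
        values,
        labels,
        feature_matrix.feature_names,
        d_max=feature_matrix.d_max,
        synthetic=synthetic_mask,
    )
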