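"""Rotation Forest ensemble with SVM subclassifiers.

Each of the L subclassifiers gets its own random partition of the
feature set into K subsets.  For every subset, a bootstrap of 75% of
the training rows (drawn with replacement) is taken, PCA is run on the
bootstrap restricted to that subset's columns, and the resulting
loading matrices are assembled into a sparse block-diagonal rotation
matrix whose rows are re-ordered back to the original feature order
(R_i^alpha).  The subclassifier — an SVM with Platt-scaled probability
outputs — is then trained on X @ R_i^alpha against the full label
vector.  Scoring averages the per-subclassifier class probabilities
("credibility"); a sample is called positive when its positive-class
credibility reaches the decision threshold (ties at the threshold go to
the positive class).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RotationForestConfig:
    """Ensemble hyperparameters.

    K: number of feature subsets per subclassifier.
    L: number of subclassifiers.
    bootstrap_fraction: fraction of rows (with replacement) fed to each
        per-subset PCA.
    pca_tolerance: eigenvalue cutoff below which components are dropped.
    svm_*: base-SVM hyperparameters (RBF kernel by default; the
        probability fit is always enabled because credibilities are
        averaged probabilities).
    """

    K: int = 20
    L: int = 5
    bootstrap_fraction: float = 0.75
    seed: int = 0
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    svm_max_iter: int = 500_000
    pca_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    def make_svm(self, random_state: int) -> SVC:
        return SVC(
            kernel=self.svm_kernel,
            C=self.svm_C,
            gamma=self.svm_gamma,
            probability=True,
            max_iter=self.svm_max_iter,
            cache_size=500,
            random_state=random_state,
        )


@dataclass
class _Subclassifier:
    partition: list[np.ndarray]
    rotation: np.ndarray  # (n_features, total retained components)
    svm: SVC


@dataclass
class RotationModel:
    """A fitted Rotation Forest: L subclassifiers with their own
    feature partitions and rotation matrices."""

    config: RotationForestConfig
    n_features: int
    members: list[_Subclassifier]


def partition_features(n_features: int, K: int, seed) -> list[np.ndarray]:
    """Randomly split {0..n_features-1} into K disjoint, exhaustive subsets.

    A seeded permutation is cut into K contiguous chunks; when K does
    not divide n_features the first (n mod K) subsets get one extra
    index.  `seed` may be an int or a Generator.
    """
    if not 1 <= K <= n_features:
        raise ValueError(f"K must be in 1..{n_features}, got {K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_features)
    base, extra = divmod(n_features, K)
    subsets, start = [], 0
    for j in range(K):
        size = base + (1 if j < extra else 0)
        subsets.append(np.sort(perm[start : start + size]))
        start += size
    return subsets


def fit_rotation(
    X: np.ndarray,
    subset_cols: np.ndarray,
    bootstrap_fraction: float,
    rng: np.random.Generator,
    pca_tolerance: float = 1e-9,
) -> np.ndarray:
    """PCA coefficient matrix C_ij for one feature subset.

    Draws ceil(bootstrap_fraction * n) rows with replacement, runs PCA
    on those rows restricted to `subset_cols`, and returns the loading
    matrix (len(subset) x m) keeping only components whose eigenvalue
    exceeds `pca_tolerance`.  A subset whose bootstrap draw is constant
    (every eigenvalue at or below tolerance) falls back to the identity.
    """
    n = X.shape[0]
    n_draw = max(2, math.ceil(bootstrap_fraction * n))
    rows = rng.integers(0, n, size=n_draw)
    sub = X[np.ix_(rows, subset_cols)]
    m = len(subset_cols)
    pca = PCA(n_components=min(m, n_draw), random_state=0)
    pca.fit(sub)
    keep = pca.explained_variance_ > pca_tolerance
    if not keep.any():
        logger.info(
            "constant bootstrap draw on a %d-feature subset: identity fallback", m
        )
        return np.eye(m)
    return pca.components_[keep].T  # columns are retained component loadings


def build_rotation_matrix(
    partition: list[np.ndarray], coefficient_matrices: list[np.ndarray]
) -> np.ndarray:
    """Assemble the block-diagonal rotation over the permuted feature
    order and re-order rows back to the original feature order.

    Row f of the result is nonzero only within the column block of the
    subset that owns feature f, so X @ R applies each subset's PCA to
    its own features.
    """
    if len(partition) != len(coefficient_matrices):
        raise ValueError("one coefficient matrix required per subset")
    n_features = sum(len(s) for s in partition)
    total_components = 0
    for subset, C in zip(partition, coefficient_matrices):
        if C.shape[0] != len(subset):
            raise ValueError(
                f"coefficient matrix rows {C.shape[0]} != subset size {len(subset)}"
            )
        total_components += C.shape[1]
    R = np.zeros((n_features, total_components))
    col = 0
    for subset, C in zip(partition, coefficient_matrices):
        R[subset, col : col + C.shape[1]] = C
        col += C.shape[1]
    return R


def fit(X: np.ndarray, y: np.ndarray, config: RotationForestConfig) -> RotationModel:
    """Train the L-member Rotation Forest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 training rows, got {X.shape[0]}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n_features = X.shape[1]
    if config.K > n_features:
        raise ValueError(f"K={config.K} exceeds n_features={n_features}")

    members = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.L)
    for i in range(config.L):
        rng = np.random.default_rng(seeds[i])
        partition = partition_features(n_features, config.K, rng)
        coeffs = [
            fit_rotation(
                X, subset, config.bootstrap_fraction, rng, config.pca_tolerance
            )
            for subset in partition
        ]
        rotation = build_rotation_matrix(partition, coeffs)
        svm = config.make_svm(random_state=int(rng.integers(0, 2**31 - 1)))
        with warnings.catch_warnings():
            # Platt-scaled probabilities are integral to the credibility
            # average; sklearn >= 1.9 warns that SVC(probability=True)
            # will move to CalibratedClassifierCV.
            warnings.filterwarnings(
                "ignore", message="The `probability` parameter", category=FutureWarning
            )
            svm.fit(X @ rotation, y)
        members.append(_Subclassifier(partition, rotation, svm))
    return RotationModel(config=config, n_features=n_features, members=members)


def predict_scores(model: RotationModel, X_new: np.ndarray) -> np.ndarray:
    """Positive-class credibility per row: the mean positive-class
    probability over the L subclassifiers, each applied to the sample
    rotated by its own R_i^alpha."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} != model dimension {model.n_features}"
        )
    total = np.zeros(X_new.shape[0])
    for member in model.members:
        proba = member.svm.predict_proba(X_new @ member.rotation)
        pos_col = int(np.flatnonzero(member.svm.classes_ == 1)[0])
        total += proba[:, pos_col]
    return total / len(model.members)


def predict_labels(
    model: RotationModel, X_new: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Binary calls: 1 iff positive-class credibility >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (predict_scores(model, X_new) >= threshold).astype(np.int64)


def save_model(model: RotationModel, path, extra: dict | None = None) -> None:
    """Serialize a fitted model (versioned container)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "model": model,
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load_model(path) -> tuple[RotationModel, dict]:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"], payload["extra"]
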