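"""Train / cross-validate / predict orchestration.

The workflow is encode -> resample -> fit -> evaluate, with model
selection over a grid of DR depths (d_max) and Rotation Forest subset
counts (K) by stratified k-fold cross-validation.  The selection
metric is the mean MCC over folds, with mean AUC and then smaller K as
tie-breaks.

Resampling runs, by default, inside each training fold only
(``resample_mode="per_fold"``): balancing the whole dataset before
splitting would place SMOTE interpolants of test points into the
training set and leak information.  A ``"global"`` mode that resamples
once before splitting is provided for protocol comparison and logs a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import ensemble, metrics, resample, seqio
from .ensemble import RotationForestConfig, RotationModel
from .features import FeatureMatrix, encode_dataset
from .metrics import MetricsReport, average_reports
from .resample import KSUConfig, SMOTEConfig
from .seqio import SiteWindow

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = tuple(range(300, 401, 10))


@dataclass(frozen=True)
class ExperimentConfig:
    residue: str = "K"
    half_width: int = 10
    d_max_grid: tuple[int, ...] = (1, 2, 3)
    K_grid: tuple[int, ...] = DEFAULT_K_GRID
    L: int = 5
    folds: int = 10
    threshold: float = 0.5
    seed: int = 0
    resample_mode: str = "per_fold"
    smote_k_neighbors: int = 5
    ksu_clusters: int = 6
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    bootstrap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.d_max_grid or not self.K_grid:
            raise ValueError("grids must be non-empty")
        if self.resample_mode not in ("per_fold", "global"):
            raise ValueError("resample_mode must be 'per_fold' or 'global'")

    def forest_config(self, K: int, seed: int) -> RotationForestConfig:
        return RotationForestConfig(
            K=K,
            L=self.L,
            bootstrap_fraction=self.bootstrap_fraction,
            seed=seed,
            svm_kernel=self.svm_kernel,
            svm_C=self.svm_C,
            svm_gamma=self.svm_gamma,
        )


@dataclass
class GridCell:
    d_max: int
    K: int
    fold_reports: list[MetricsReport]
    mean_report: MetricsReport


@dataclass
class CVResult:
    cells: dict[tuple[int, int], GridCell]
    selected: tuple[int, int]
    selection_criterion: str

    @property
    def selected_cell(self) -> GridCell:
        return self.cells[self.selected]

    def to_table(self) -> pd.DataFrame:
        """One row per (d_max, K) cell, metric columns in display order."""
        rows = []
        for (d_max, K), cell in sorted(self.cells.items()):
            row = {"d_max": d_max, "K": K}
            row.update(cell.mean_report.as_dict(rounded=True))
            rows.append(row)
        return pd.DataFrame(rows)


def _resample_training(
    fm: FeatureMatrix, config: ExperimentConfig, seed: int
) -> FeatureMatrix:
    n1, n0 = fm.class_counts()
    if n0 <= n1:
        logger.info(
            "training set already balanced or positive-heavy (%d pos, %d neg); "
            "skipping resampling", n1, n0,
        )
        return fm
    plan = resample.compute_plan(n1, n0)
    return resample.smote_ksu(
        fm,
        plan,
        SMOTEConfig(k_neighbors=config.smote_k_neighbors, seed=seed),
        KSUConfig(n_clusters=config.ksu_clusters, seed=seed + 1),
    )


def _subset(fm: FeatureMatrix, rows: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        fm.values[rows], fm.labels[rows], fm.feature_names, d_max=fm.d_max
    )


def cross_validate(windows: list[SiteWindow], config: ExperimentConfig) -> CVResult:
    """Stratified k-fold CV over the (d_max, K) grid.

    Held-out folds are never resampled; in ``per_fold`` mode the
    training folds are re-balanced independently within each split.
    Grid cells whose K exceeds the feature dimension are skipped with a
    logged notice.
    """
    labels = np.array([w.label for w in windows])
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if min(n1, n0) < config.folds:
        raise ValueError(
            f"smallest class has {min(n1, n0)} members; use at most that many folds"
        )

    cells: dict[tuple[int, int], GridCell] = {}
    for d_max in config.d_max_grid:
        fm = encode_dataset(windows, d_max)
        if config.resample_mode == "global":
            logger.warning(
                "global resampling before CV leaks synthetic neighbours of "
                "held-out points into training; interpret results accordingly"
            )
            fm = _resample_training(fm, config, seed=config.seed)
        splitter = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed
        )
        splits = list(splitter.split(fm.values, fm.labels))
        for K in config.K_grid:
            if K > fm.n_features:
                logger.info(
                    "skipping grid cell (d_max=%d, K=%d): only %d features",
                    d_max, K, fm.n_features,
                )
                continue
            fold_reports = []
            for fold_no, (train_idx, test_idx) in enumerate(splits):
                train = _subset(fm, train_idx)
                test = _subset(fm, test_idx)
                if config.resample_mode == "per_fold":
                    train = _resample_training(
                        train, config, seed=config.seed * 1000 + fold_no
                    )
                model = ensemble.fit(
                    train.values,
                    train.labels,
                    config.forest_config(K, seed=config.seed * 1000 + fold_no),
                )
                scores = ensemble.predict_scores(model, test.values)
                fold_reports.append(
                    metrics.evaluate(test.labels, scores, config.threshold)
                )
            cells[(d_max, K)] = GridCell(
                d_max, K, fold_reports, average_reports(fold_reports)
            )
    if not cells:
        raise ValueError("every grid cell was skipped (K grid exceeds feature dims)")

    def sort_key(item):
        (d_max, K), cell = item
        mcc = cell.mean_report.mcc
        auc = cell.mean_report.auc
        return (
            -(mcc if np.isfinite(mcc) else -np.inf),
            -(auc if np.isfinite(auc) else -np.inf),
            K,
        )

    selected = min(cells.items(), key=sort_key)[0]
    return CVResult(
        cells=cells,
        selected=selected,
        selection_criterion="max mean MCC, ties by mean AUC then smaller K",
    )


@dataclass
class ModelBundle:
    """A trained model plus everything needed to score new proteins."""

    model: RotationModel
    residue: str
    half_width: int
    d_max: int
    threshold: float


def train_final(
    windows: list[SiteWindow],
    config: ExperimentConfig,
    selected_cell: tuple[int, int],
) -> ModelBundle:
    """Resample the full training set and fit one model at the selected
    (d_max, K)."""
    d_max, K = selected_cell
    if d_max not in config.d_max_grid or K not in config.K_grid:
        raise ValueError(f"selected cell {selected_cell} outside the configured grids")
    fm = encode_dataset(windows, d_max)
    balanced = _resample_training(fm, config, seed=config.seed)
    model = ensemble.fit(
        balanced.values, balanced.labels, config.forest_config(K, seed=config.seed)
    )
    return ModelBundle(
        model=model,
        residue=config.residue,
        half_width=config.half_width,
        d_max=d_max,
        threshold=config.threshold,
    )


def save_bundle(bundle: ModelBundle, path) -> None:
    ensemble.save_model(
        bundle.model,
        path,
        extra={
            "residue": bundle.residue,
            "half_width": bundle.half_width,
            "d_max": bundle.d_max,
            "threshold": bundle.threshold,
        },
    )


def load_bundle(path) -> ModelBundle:
    model, extra = ensemble.load_model(path)
    return ModelBundle(model=model, **extra)


def predict_proteins(
    bundle: ModelBundle, fasta_path, threshold: float | None = None
) -> pd.DataFrame:
    """Score every candidate residue of every protein in a FASTA file.

    Returns the prediction table (protein_id, position, residue, score,
    call) sorted by protein then position; a protein without the target
    residue contributes no rows (logged).
    """
    threshold = bundle.threshold if threshold is None else threshold
    proteins = seqio.read_fasta(fasta_path)
    frames = []
    for protein in proteins:
        sites = seqio.scan_candidate_sites(protein, bundle.residue)
        if not sites:
            logger.info("protein %s has no %s residues", protein.id, bundle.residue)
            continue
        windows = seqio.extract_windows([protein], sites, bundle.half_width)
        fm = encode_dataset(windows, bundle.d_max)
        scores = ensemble.predict_scores(bundle.model, fm.values)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": protein.id,
                    "position": [s.position for s in sites],
                    "residue": bundle.residue,
                    "score": scores,
                    "call": (scores >= threshold).astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=seqio.PREDICTION_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["protein_id", "position"], ignore_index=True)
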