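"""Stratified cross-validation, SMOTE class balancing, and evaluation metrics.

The malignancy dataset is imbalanced (roughly 2:1 benign to malignant), so
inside every cross-validation training fold the minority class is brought to
parity with SMOTE: each synthetic sample is a convex combination
``x + u * (x_nn - x)`` of a minority point and one of its k nearest minority
neighbors.  Synthetic samples never enter a test fold — this is asserted on
every run.

Metrics follow the standard contingency-table definitions: recall
TP/(TP+FN), precision TP/(TP+FP), accuracy (TP+TN)/total, and F1 the
harmonic mean of precision and recall.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from . import unet4d
from .unet4d import Tensor4DSample, UNetConfig


@dataclass
class FoldPlan:
    """A stratified partition of samples into folds."""

    n_folds: int
    assignments: np.ndarray  # sample index -> fold id
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment: per-fold class proportions within one
    sample of the global proportions; deterministic given the seed."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = counts < n_folds
    if small.any():
        raise ValueError(
            f"class {classes[small][0]!r} has fewer members than n_folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_oversample(
    minority: np.ndarray,
    majority_count: int,
    cfg: SmoteConfig = SmoteConfig(),
) -> np.ndarray:
    """Generate ``majority_count - len(minority)`` synthetic minority samples.

    Each synthetic point is x + u * (x_nn - x) with x a uniformly chosen
    minority point, x_nn one of x's k nearest minority neighbors (excluding
    itself) and u ~ Uniform[0, 1]; fully seeded.  Balanced classes yield an
    empty array.
    """
    minority = np.asarray(minority, dtype=np.float64)
    if minority.ndim != 2:
        raise ValueError("minority must be (n_samples, n_features)")
    n_min = len(minority)
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors="
            f"{cfg.k_neighbors}; use a smaller k"
        )
    n_new = majority_count - n_min
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(minority)
    neigh = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = minority[base]
    x_nn = minority[neigh[base, pick]]
    return x + u[:, None] * (x_nn - x)


@dataclass(frozen=True)
class ContingencyCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.FN + other.FN, self.TN + other.TN,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Recall, precision, accuracy and F1 as fractions in [0, 1]."""

    recall: float
    precision: float
    accuracy: float
    f1: float

    def as_percent(self) -> dict:
        return {
            k: round(100.0 * v, 2)
            for k, v in (
                ("recall", self.recall), ("precision", self.precision),
                ("accuracy", self.accuracy), ("f1", self.f1),
            )
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ContingencyCounts) -> MetricsReport:
    """The four contingency-table metrics; zero denominators report 0."""
    if counts.total == 0:
        raise ValueError("empty contingency table")
    recall = _safe_div(counts.TP, counts.TP + counts.FN, "recall")
    precision = _safe_div(counts.TP, counts.TP + counts.FP, "precision")
    accuracy = counts.TP + counts.TN
    accuracy = accuracy / counts.total
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(recall=recall, precision=precision,
                         accuracy=accuracy, f1=f1)


def counts_from_predictions(y_true, y_pred, positive: int = 1) -> ContingencyCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ContingencyCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass
class CrossValResult:
    per_fold: list[MetricsReport]
    pooled: MetricsReport
    pooled_counts: ContingencyCounts
    histories: list[list[dict]] = field(default_factory=list)


def _flatten(sample: Tensor4DSample) -> np.ndarray:
    return np.concatenate(
        [sample.volume.ravel(), sample.shape_matrix.ravel()]
    ).astype(np.float64)


def _unflatten(vec: np.ndarray, like: Tensor4DSample, label: int) -> Tensor4DSample:
    nv = like.volume.size
    vol = vec[:nv].reshape(like.volume.shape)
    mat = vec[nv:].reshape(like.shape_matrix.shape)
    return Tensor4DSample(volume=np.clip(vol, 0.0, 1.0),
                          shape_matrix=np.clip(mat, 0.0, 1.0), label=label)


def cross_validate(
    samples: list[Tensor4DSample],
    unet_cfg: UNetConfig,
    fold_plan: FoldPlan,
    smote_cfg: SmoteConfig | None = SmoteConfig(),
    positive: int = 1,
) -> CrossValResult:
    """Train-and-test over every fold with SMOTE confined to training data.

    For each fold the held-out samples are untouched; the training portion is
    balanced by SMOTE in the flattened (volume + shape-matrix) feature space,
    a fresh seeded model is trained, and test-fold predictions update the
    fold's contingency table.  Pooled metrics aggregate raw counts across
    folds.  A leakage assertion guarantees no synthetic sample reaches a
    test fold.
    """
    labels = np.asarray([s.label for s in samples])
    per_fold: list[MetricsReport] = []
    histories = []
    pooled = ContingencyCounts(0, 0, 0, 0)
    in_extents = (2, *samples[0].volume.shape)
    for fold in range(fold_plan.n_folds):
        test_idx = fold_plan.test_indices(fold)
        train_idx = fold_plan.train_indices(fold)
        train_samples = [samples[i] for i in train_idx]
        test_samples = [samples[i] for i in test_idx]
        if smote_cfg is not None:
            train_samples = train_samples + _smote_augment(
                train_samples, labels[train_idx], smote_cfg, fold
            )
        # leakage guard: the test fold must consist of original samples only
        assert all(samples[i] is test_samples[k]
                   for k, i in enumerate(test_idx)), \
            "synthetic sample leaked into a test fold"
        cfg = dataclasses.replace(unet_cfg, seed=unet_cfg.seed + 1000 * fold)
        model = unet4d.build_unet(cfg, in_extents=in_extents)
        model, hist = unet4d.train(model, train_samples, cfg)
        histories.append(hist)
        probs = unet4d.predict(model, test_samples)
        y_pred = probs.argmax(axis=1)
        counts = counts_from_predictions(labels[test_idx], y_pred, positive)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts
    return CrossValResult(
        per_fold=per_fold, pooled=compute_metrics(pooled),
        pooled_counts=pooled, histories=histories,
    )


def _smote_augment(train_samples, train_labels, smote_cfg, fold):
    """SMOTE in flattened feature space, returned as new Tensor4DSamples."""
    classes, counts = np.unique(train_labels, return_counts=True)
    if len(classes) < 2 or counts.min() == counts.max():
        return []
    minority_label = classes[np.argmin(counts)]
    minority = [s for s in train_samples if s.label == minority_label]
    feats = np.stack([_flatten(s) for s in minority])
    cfg = SmoteConfig(k_neighbors=smote_cfg.k_neighbors,
                      seed=smote_cfg.seed + 7919 * fold)
    synth = smote_oversample(feats, int(counts.max()), cfg)
    return [_unflatten(v, minority[0], int(minority_label)) for v in synth]
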