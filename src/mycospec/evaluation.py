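"""Kennard-Stone partitioning, accuracy reporting, and model comparison.

Kennard-Stone (KS) is the classic deterministic max-min selector: the
first two picks are the most distant pair, and every later pick
maximizes its minimum Euclidean distance to the already-selected set.
The training partition is KS-selected (per class by default, in SNV
space) at a 4:1 train:test ratio, so both partitions span the spectral
variability without randomness.

Accuracy is the fraction of correctly classified samples; per-class
TP/TN/FP/FN counts come from a one-vs-rest collapse of the multiclass
confusion matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import confusion_matrix

from .calibration import SpectrumSet
from .preprocessing import snv

__all__ = [
    "SplitIndices",
    "ClassificationReport",
    "kennard_stone",
    "ks_split",
    "evaluate",
    "run_comparison",
]


@dataclasses.dataclass
class SplitIndices:
    """Disjoint train/test sample-id lists."""

    train_ids: list
    test_ids: list
    ratio: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclasses.dataclass
class ClassificationReport:
    """Confusion matrix, accuracy, and one-vs-rest per-class counts."""

    confusion: np.ndarray
    classes: np.ndarray
    accuracy: float
    per_class: pd.DataFrame


def kennard_stone(X, n_select: int) -> np.ndarray:
    """Ordered KS selection of ``n_select`` row indices of ``X``.

    Ties break toward the lowest index, so the selection is fully
    deterministic and permutation-covariant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}]")
    D = cdist(X, X)
    if D.max() == 0:
        raise ValueError("all points coincide; KS selection is undefined")
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)  # first max: lowest (i, j)
    selected = [int(min(i, j)), int(max(i, j))]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_select:
        min_dist[selected] = -np.inf
        k = int(np.argmax(min_dist))
        selected.append(k)
        min_dist = np.minimum(min_dist, D[k])
    return np.array(selected, dtype=int)


def ks_split(
    spectra: SpectrumSet,
    ratio: float = 0.8,
    stratified: bool = True,
    distance_space: str = "snv",
) -> SplitIndices:
    """Deterministic KS train/test split of a spectrum set.

    In stratified mode (default) KS runs inside each class; distances are
    computed on SNV-preprocessed spectra unless ``distance_space='raw'``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if distance_space not in ("snv", "raw"):
        raise ValueError("distance_space must be 'snv' or 'raw'")
    X = snv(spectra.spectra) if distance_space == "snv" else spectra.spectra
    ids = spectra.sample_ids
    train_ids: list = []
    if stratified:
        for label in np.unique(spectra.labels):
            rows = np.flatnonzero(spectra.labels == label)
            n_c = rows.size
            n_train = int(round(ratio * n_c))
            if not 2 <= n_train <= n_c - 1:
                raise ValueError(
                    f"class {label} has {n_c} samples; cannot take "
                    f"{n_train} for training at ratio {ratio}"
                )
            picked = rows[kennard_stone(X[rows], n_train)]
            train_ids.extend(ids[picked])
    else:
        n_train = int(round(ratio * spectra.n_samples))
        if not 2 <= n_train <= spectra.n_samples - 1:
            raise ValueError("ratio leaves no test (or no train) samples")
        picked = kennard_stone(X, n_train)
        train_ids.extend(ids[picked])
    train_set = set(train_ids)
    test_ids = [sid for sid in ids if sid not in train_set]
    return SplitIndices(train_ids=list(train_ids), test_ids=test_ids, ratio=ratio)


def evaluate(predictions, truth, classes=None) -> ClassificationReport:
    """Multiclass accuracy and one-vs-rest per-class counts."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([truth, predictions]))
    classes = np.asarray(classes)
    cm = confusion_matrix(truth, predictions, labels=classes)
    total = int(cm.sum())
    accuracy = float(np.trace(cm)) / total
    rows = []
    for k, cls in enumerate(classes):
        tp = int(cm[k, k])
        fn = int(cm[k].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        tn = total - tp - fn - fp
        rows.append({"class": cls, "TP": tp, "TN": tn, "FP": fp, "FN": fn})
    return ClassificationReport(
        confusion=cm, classes=classes, accuracy=accuracy, per_class=pd.DataFrame(rows)
    )


def run_comparison(config, seed: int | None = None):
    """Run the full synthetic experiment grid.

    Executes the end-to-end pipeline (generate, calibrate, preprocess,
    select bands, extract image features, train, evaluate) and returns a
    :class:`~mycospec.pipeline.ComparisonResult` holding

    * a pretreatment table — {none, SG, MSC, SNV} x full-spectrum SVM;
    * a model table — raw-spectrum, SPA-spectrum, raw-image,
      backend-image-feature, and fused-kernel SVMs;

    plus the band selection, the split, per-model reports, and the
    configurations of every cell.
    """
    from .pipeline import run_comparison as _run

    return _run(config, seed=seed)
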