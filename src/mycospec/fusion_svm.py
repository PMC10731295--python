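"""Precomputed-kernel SVM with convex spectral + image kernel fusion.

Two RBF Gram matrices are built — one on the (band-selected) spectral
features, one on the image features — and combined convexly,

    K = mu * Ks + (1 - mu) * Kw,     0 <= mu <= 1,

then fed to a standard C-SVM solved in the dual (one-vs-one for
multiclass). ``mu = 1`` reduces bit-for-bit to the spectral-only model
and ``mu = 0`` to the image-only model, so single-modality baselines are
endpoints of the same code path. ``mu``, ``C`` and the two RBF widths
are chosen by stratified cross-validated grid search on the training
partition only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "KernelConfig",
    "FusedKernelModel",
    "KernelPSDError",
    "rbf_gram",
    "fuse",
    "fit",
    "dual_feasibility",
    "train_fused",
    "predict",
    "grid_search",
]

DEFAULT_MU_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.1, 1.0)


class KernelPSDError(ValueError):
    """Raised when a training kernel is not positive semidefinite."""


@dataclasses.dataclass(frozen=True)
class KernelConfig:
    """Fusion weight, RBF widths, and SVM regularization."""

    mu: float = 0.5
    gamma_s: float = 0.1
    gamma_w: float = 0.1
    C: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.gamma_s <= 0 or self.gamma_w <= 0:
            raise ValueError("RBF widths must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


def rbf_gram(A, B, gamma: float) -> np.ndarray:
    """RBF Gram matrix ``K[i, j] = exp(-gamma * ||a_i - b_j||^2)``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature widths differ")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite feature values")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


def fuse(Ks: np.ndarray, Kw: np.ndarray, mu: float) -> np.ndarray:
    """Convex combination ``mu * Ks + (1 - mu) * Kw`` elementwise."""
    Ks = np.asarray(Ks, dtype=float)
    Kw = np.asarray(Kw, dtype=float)
    if Ks.shape != Kw.shape:
        raise ValueError("Gram matrices must share a shape")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    return mu * Ks + (1.0 - mu) * Kw


def _check_train_kernel(K: np.ndarray, psd_tol: float) -> None:
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("training kernel must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("training kernel must be symmetric")
    min_eig = float(np.linalg.eigvalsh(K).min())
    if min_eig < -psd_tol * max(1.0, float(np.abs(K).max())):
        raise KernelPSDError(
            f"training kernel has negative eigenvalue {min_eig:.3e}; "
            "clip negative eigenvalues or revisit the kernel parameters"
        )


def fit(K_train: np.ndarray, labels, C: float, psd_tol: float = 1e-8, tol: float = 1e-3) -> SVC:
    """Fit a one-vs-one precomputed-kernel C-SVM on a fused Gram matrix.

    The kernel is checked for symmetry and positive semidefiniteness and
    the fitted dual coefficients are verified against the box and
    equality constraints of the dual problem.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("at least two classes are required")
    K_train = np.asarray(K_train, dtype=float)
    _check_train_kernel(K_train, psd_tol)
    svc = SVC(C=C, kernel="precomputed", tol=tol)
    svc.fit(K_train, labels)
    ok, report = dual_feasibility(svc)
    if not ok:  # pragma: no cover - solver contract violation
        raise RuntimeError(f"SVM dual constraints violated: {report}")
    return svc


def dual_feasibility(svc: SVC, tol: float = 1e-6) -> tuple:
    """Check 0 <= alpha_i <= C and sum(alpha_i y_i) = 0 per binary subproblem.

    sklearn's one-vs-one ``dual_coef_`` stores ``y_i * alpha_i``; for the
    pair (a, b) the relevant entries are row ``b - 1`` (if ``b > a``,
    else ``b``) of the class-a support vectors together with the matching
    row of the class-b support vectors, and their total must vanish.
    """
    coef = svc.dual_coef_
    c_bound = float(svc.C)
    if np.any(np.abs(coef) > c_bound + tol):
        return False, f"|alpha| exceeds C={c_bound}"
    n_classes = len(svc.classes_)
    starts = np.concatenate([[0], np.cumsum(svc.n_support_)])
    worst = 0.0
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            row_a = b - 1  # position of b among a's opponents
            row_b = a  # position of a among b's opponents (a < b)
            s = coef[row_a, starts[a] : starts[a + 1]].sum()
            s += coef[row_b, starts[b] : starts[b + 1]].sum()
            worst = max(worst, abs(float(s)))
    if worst > tol * max(1.0, c_bound):
        return False, f"sum(alpha_i y_i) = {worst:.3e} != 0"
    return True, f"max |sum(alpha y)| = {worst:.3e}"


@dataclasses.dataclass
class FusedKernelModel:
    """Trained fused-kernel SVM plus everything needed to kernelize new data."""

    config: KernelConfig
    svc: SVC
    train_spectral: np.ndarray  # standardized training feature blocks
    train_image: np.ndarray
    spectral_scaler: tuple | None  # (mean, sd) or None
    image_scaler: tuple | None
    training_sample_ids: np.ndarray
    training_labels: np.ndarray

    @property
    def classes_(self) -> np.ndarray:
        return self.svc.classes_

    @property
    def dual_coefficients(self) -> np.ndarray:
        return self.svc.dual_coef_

    @property
    def intercepts(self) -> np.ndarray:
        return self.svc.intercept_


def _fit_scaler(X: np.ndarray) -> tuple:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _apply_scaler(X: np.ndarray, scaler: tuple | None) -> np.ndarray:
    if scaler is None:
        return np.asarray(X, dtype=float)
    mean, sd = scaler
    return (np.asarray(X, dtype=float) - mean) / sd


def resolve_gamma(gamma, X: np.ndarray) -> float:
    """Resolve 'scale' (1 / (d * var)) to a number; pass numbers through."""
    if isinstance(gamma, str):
        if gamma != "scale":
            raise ValueError(f"unknown gamma spec {gamma!r}")
        var = float(np.asarray(X, dtype=float).var())
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(gamma)


def train_fused(
    spectral: np.ndarray,
    image: np.ndarray,
    labels,
    config: KernelConfig,
    standardize: bool = True,
    sample_ids=None,
) -> FusedKernelModel:
    """Standardize, kernelize, fuse, and fit the final model."""
    spectral = np.asarray(spectral, dtype=float)
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if spectral.shape[0] != image.shape[0] or spectral.shape[0] != labels.size:
        raise ValueError("spectral/image/label row counts differ")
    s_scaler = _fit_scaler(spectral) if standardize else None
    w_scaler = _fit_scaler(image) if standardize else None
    Xs = _apply_scaler(spectral, s_scaler)
    Xw = _apply_scaler(image, w_scaler)
    K = fuse(
        rbf_gram(Xs, Xs, config.gamma_s),
        rbf_gram(Xw, Xw, config.gamma_w),
        config.mu,
    )
    svc = fit(K, labels, config.C)
    if sample_ids is None:
        sample_ids = np.arange(labels.size)
    return FusedKernelModel(
        config=config,
        svc=svc,
        train_spectral=Xs,
        train_image=Xw,
        spectral_scaler=s_scaler,
        image_scaler=w_scaler,
        training_sample_ids=np.asarray(sample_ids, dtype=object),
        training_labels=labels.copy(),
    )


def predict(model: FusedKernelModel, spectral: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Labels for new samples via cross-Gram blocks against the training set."""
    spectral = np.atleast_2d(np.asarray(spectral, dtype=float))
    image = np.atleast_2d(np.asarray(image, dtype=float))
    if spectral.shape[1] != model.train_spectral.shape[1]:
        raise ValueError("spectral feature width does not match training")
    if image.shape[1] != model.train_image.shape[1]:
        raise ValueError("image feature width does not match training")
    Xs = _apply_scaler(spectral, model.spectral_scaler)
    Xw = _apply_scaler(image, model.image_scaler)
    K = fuse(
        rbf_gram(Xs, model.train_spectral, model.config.gamma_s),
        rbf_gram(Xw, model.train_image, model.config.gamma_w),
        model.config.mu,
    )
    return model.svc.predict(K)


def grid_search(
    spectral: np.ndarray,
    image: np.ndarray,
    labels,
    mu_grid=DEFAULT_MU_GRID,
    C_grid=DEFAULT_C_GRID,
    gamma_s_grid=DEFAULT_GAMMA_GRID,
    gamma_w_grid=DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> tuple:
    """Stratified k-fold CV accuracy over the full parameter grid.

    Returns ``(best KernelConfig, cv_table)``; the table holds one row
    per grid point with its CV accuracy. Ties break toward smaller C,
    then larger mu (favoring the spectral kernel), then smaller widths.
    Scalers and 'scale' gamma values are resolved inside each training
    fold; the returned config carries gammas resolved on the full
    training partition.
    """
    spectral = np.asarray(spectral, dtype=float)
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if not (len(mu_grid) and len(C_grid) and len(gamma_s_grid) and len(gamma_w_grid)):
        raise ValueError("parameter grids must be non-empty")
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < cv_folds:
        raise ValueError(
            f"the rarest class has {counts.min()} samples; use at most that many folds"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(spectral, labels))

    keys = [
        (mu, C, gs, gw)
        for gs in gamma_s_grid
        for gw in gamma_w_grid
        for mu in mu_grid
        for C in C_grid
    ]
    correct = {k: 0 for k in keys}
    total = 0
    for train_idx, test_idx in folds:
        y_tr, y_te = labels[train_idx], labels[test_idx]
        total += test_idx.size
        s_scaler = _fit_scaler(spectral[train_idx]) if standardize else None
        w_scaler = _fit_scaler(image[train_idx]) if standardize else None
        Xs_tr = _apply_scaler(spectral[train_idx], s_scaler)
        Xs_te = _apply_scaler(spectral[test_idx], s_scaler)
        Xw_tr = _apply_scaler(image[train_idx], w_scaler)
        Xw_te = _apply_scaler(image[test_idx], w_scaler)
        grams_s = {}
        for gs in gamma_s_grid:
            g = resolve_gamma(gs, Xs_tr)
            grams_s[gs] = (rbf_gram(Xs_tr, Xs_tr, g), rbf_gram(Xs_te, Xs_tr, g))
        grams_w = {}
        for gw in gamma_w_grid:
            g = resolve_gamma(gw, Xw_tr)
            grams_w[gw] = (rbf_gram(Xw_tr, Xw_tr, g), rbf_gram(Xw_te, Xw_tr, g))
        for gs in gamma_s_grid:
            Ks_tr, Ks_te = grams_s[gs]
            for gw in gamma_w_grid:
                Kw_tr, Kw_te = grams_w[gw]
                for mu in mu_grid:
                    K_tr = fuse(Ks_tr, Kw_tr, mu)
                    K_te = fuse(Ks_te, Kw_te, mu)
                    for C in C_grid:
                        svc = SVC(C=C, kernel="precomputed")
                        svc.fit(K_tr, y_tr)
                        correct[(mu, C, gs, gw)] += int((svc.predict(K_te) == y_te).sum())

    rows = [
        {
            "mu": mu,
            "C": C,
            "gamma_s": gs,
            "gamma_w": gw,
            "cv_accuracy": correct[(mu, C, gs, gw)] / total,
        }
        for (mu, C, gs, gw) in keys
    ]
    cv_table = pd.DataFrame(rows)

    def sort_key(k):
        mu, C, gs, gw = k
        acc = correct[k] / total
        g_s = resolve_gamma(gs, spectral)
        g_w = resolve_gamma(gw, image)
        return (-acc, C, -mu, g_s, g_w)

    best_mu, best_c, best_gs, best_gw = min(keys, key=sort_key)
    s_scaler = _fit_scaler(spectral) if standardize else None
    w_scaler = _fit_scaler(image) if standardize else None
    best = KernelConfig(
        mu=float(best_mu),
        gamma_s=resolve_gamma(best_gs, _apply_scaler(spectral, s_scaler)),
        gamma_w=resolve_gamma(best_gw, _apply_scaler(image, w_scaler)),
        C=float(best_c),
    )
    return best, cv_table
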