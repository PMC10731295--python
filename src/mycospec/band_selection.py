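"""Successive projections algorithm (SPA) wavelength selection.

SPA is a greedy, collinearity-minimizing variable selector. Starting from
a chosen band, every unselected band (a column of the spectra matrix) is
repeatedly replaced by its projection onto the orthogonal complement of
the most recently selected (projected) band, and the band of maximal
Euclidean norm is selected next. Because the deflations compose, each
selected column is orthogonal to the span of all its predecessors.

The number of bands N is picked by cross-validated RMSE of a multiple
linear regression of the ordinal grade label on the selected bands,
sweeping candidate chain lengths (and, by default, every possible start
band) and keeping the minimum-RMSE combination.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.model_selection import KFold

from .calibration import SpectrumSet

__all__ = [
    "BandSelection",
    "CollinearityError",
    "spa_chain",
    "select_bands",
    "apply_selection",
]

_NORM_TOL = 1e-12


class CollinearityError(RuntimeError):
    """Raised when the remaining projected bands are numerically collinear."""


@dataclasses.dataclass
class BandSelection:
    """Result of SPA band selection."""

    selected_indices: list
    selected_wavelengths_nm: list
    start_index: int
    n_bands: int
    rmse_curve: dict  # candidate N -> min-over-starts CV RMSE
    chosen_rmse: float

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be distinct")
        if len(self.selected_indices) != self.n_bands:
            raise ValueError("n_bands must equal the number of selected indices")


def spa_chain(X, start: int, N: int) -> list:
    """Run the SPA projection chain and return the ordered band indices.

    ``X`` is an ``n_samples x n_bands`` matrix; the chain begins at band
    ``start`` and greedily selects ``N`` bands. Ties in the projected norm
    are broken by the lowest band index, so the chain is deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, b = X.shape
    if not 0 <= start < b:
        raise ValueError(f"start band {start} out of range for {b} bands")
    if not 1 <= N <= min(n - 1, b):
        raise ValueError(f"N must be in [1, min(n-1, B)] = [1, {min(n - 1, b)}]")
    norms0 = np.linalg.norm(X, axis=0)
    if np.any(norms0 <= _NORM_TOL):
        raise ValueError("X has an all-zero band column")

    work = X.copy()
    selected = [int(start)]
    unselected = [j for j in range(b) if j != start]
    for _ in range(1, N):
        v = work[:, selected[-1]]
        vv = float(v @ v)
        if vv <= _NORM_TOL**2:
            raise CollinearityError(
                f"projected reference band vanished; achievable N = {len(selected)}"
            )
        cols = work[:, unselected]
        cols -= np.outer(v, (v @ cols) / vv)
        work[:, unselected] = cols
        norms = np.linalg.norm(cols, axis=0)
        best = float(norms.max())
        if best < _NORM_TOL:
            raise CollinearityError(
                f"all remaining projected norms are below {_NORM_TOL}; "
                f"achievable N = {len(selected)}"
            )
        # argmax returns the first maximum; `unselected` is kept in
        # ascending order, so ties resolve to the lowest band index.
        k = unselected[int(np.argmax(norms))]
        selected.append(k)
        unselected.remove(k)
    return selected


def _cv_rmse(X: np.ndarray, y: np.ndarray, folds: list) -> float:
    """K-fold CV RMSE of ordinary least squares y ~ 1 + X."""
    sq_sum = 0.0
    n_total = 0
    for train_idx, test_idx in folds:
        a_train = np.column_stack([np.ones(train_idx.size), X[train_idx]])
        a_test = np.column_stack([np.ones(test_idx.size), X[test_idx]])
        try:
            coef, *_ = np.linalg.lstsq(a_train, y[train_idx], rcond=None)
        except np.linalg.LinAlgError:
            return np.inf
        resid = a_test @ coef - y[test_idx]
        if not np.all(np.isfinite(resid)):
            return np.inf
        sq_sum += float(resid @ resid)
        n_total += test_idx.size
    return float(np.sqrt(sq_sum / n_total))


def select_bands(
    train_spectra: SpectrumSet,
    n_min: int = 1,
    n_max: int = 16,
    cv_folds: int = 5,
    seed: int = 0,
    starts: int | None = None,
) -> BandSelection:
    """Choose the SPA chain length (and start band) by CV RMSE.

    For every start band (all bands by default; an integer ``starts``
    draws a seeded subsample for speed) one chain of length ``n_max`` is
    built; its prefixes provide every candidate N in ``[n_min, n_max]``.
    Each candidate is scored by k-fold CV RMSE of a linear regression of
    the numeric grade label on the selected bands. Ties break toward the
    smallest N, then the smallest start index.
    """
    X = train_spectra.spectra
    y = train_spectra.labels.astype(float)
    n, b = X.shape
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    smallest_train_fold = n - int(np.ceil(n / cv_folds))
    if n_max >= smallest_train_fold:
        raise ValueError(
            f"n_max={n_max} must be below the smallest CV training-fold size "
            f"({smallest_train_fold})"
        )
    if starts is None:
        start_list = list(range(b))
    else:
        rng = np.random.default_rng(seed)
        start_list = sorted(rng.choice(b, size=min(int(starts), b), replace=False).tolist())

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    candidates = range(n_min, n_max + 1)
    best_rmse = {N: np.inf for N in candidates}
    best_chain = {N: None for N in candidates}
    best_start = {N: None for N in candidates}
    for start in start_list:
        try:
            chain = spa_chain(X, start, n_max)
        except CollinearityError:
            continue
        for N in candidates:
            idx = chain[:N]
            rmse = _cv_rmse(X[:, idx], y, folds)
            if rmse < best_rmse[N]:
                best_rmse[N] = rmse
                best_chain[N] = idx
                best_start[N] = start

    feasible = [N for N in candidates if np.isfinite(best_rmse[N])]
    if not feasible:
        raise CollinearityError("no feasible SPA candidate; data too collinear")
    chosen_n = min(feasible, key=lambda N: (best_rmse[N], N))
    chain = best_chain[chosen_n]
    return BandSelection(
        selected_indices=list(chain),
        selected_wavelengths_nm=train_spectra.wavelengths_nm[chain].tolist(),
        start_index=int(best_start[chosen_n]),
        n_bands=chosen_n,
        rmse_curve={int(N): float(best_rmse[N]) for N in candidates},
        chosen_rmse=float(best_rmse[chosen_n]),
    )


def apply_selection(spectra: SpectrumSet, selection: BandSelection) -> SpectrumSet:
    """Restrict a spectrum set to the selected bands, in chain order."""
    idx = np.asarray(selection.selected_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= spectra.n_bands):
        raise IndexError(
            f"selection indices exceed the spectrum width ({spectra.n_bands})"
        )
    return spectra.subset_bands(idx)
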