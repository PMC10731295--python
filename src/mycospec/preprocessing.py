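"""Spectral pretreatments: SNV, MSC, and Savitzky-Golay smoothing.

All three operate row-wise on an ``n_samples x n_bands`` matrix (a single
spectrum is accepted wherever that makes sense). MSC is the only method
with shared state: a reference spectrum, by default the mean of the
matrix it is fitted on. In a train/test workflow the reference must be
computed on the training partition and reused for test spectra.

Conventions (the sources of these methods leave them open):

* SNV uses the sample standard deviation (``n - 1`` denominator).
* Savitzky-Golay edges are handled by evaluating the polynomial fitted
  to the nearest full window (``mode="interp"``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter

from .calibration import SpectrumSet

__all__ = ["PreprocessConfig", "snv", "msc", "sg_smooth", "preprocess"]

_METHODS = ("none", "sg", "msc", "snv")


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Which pretreatment to run, with its parameters."""

    method: str = "snv"
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference: str = "dataset_mean"  # or a fixed reference vector

    def __post_init__(self) -> None:
        if self.method.lower() not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be below sg_window")


def _rows(spectra) -> tuple:
    x = np.asarray(spectra, dtype=float)
    was_1d = x.ndim == 1
    return np.atleast_2d(x), was_1d


def snv(spectra, sd_tol: float = 1e-12):
    """Standard normal variate: center and scale each spectrum separately.

    ``(x - mean(x)) / sd(x)`` with the sample (n-1) standard deviation.
    Constant spectra are rejected.
    """
    x, was_1d = _rows(spectra)
    if x.shape[1] < 2:
        raise ValueError("SNV needs spectra of length >= 2")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() <= sd_tol)
    if bad.size:
        raise ValueError(
            f"SNV is undefined for (near-)constant spectra; offending row(s): {bad.tolist()}"
        )
    out = (x - mean) / sd
    return out[0] if was_1d else out


def msc(spectra, reference=None, slope_tol: float = 1e-8):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference, ``x ~ a + b*ref``
    (ordinary least squares), and corrected as ``(x - a) / b``. With no
    explicit reference the column mean of ``spectra`` is the "ideal
    spectrum".
    """
    x, was_1d = _rows(spectra)
    if reference is None:
        if x.shape[0] < 2:
            raise ValueError("dataset-mean MSC needs at least 2 spectra")
        reference = x.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (x.shape[1],):
        raise ValueError("reference length must match the spectra width")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < slope_tol)
    if bad.size:
        raise ValueError(
            f"MSC slope is degenerate (|b| < {slope_tol}) for row(s): {bad.tolist()}"
        )
    a = x.mean(axis=1) - b * ref.mean()
    out = (x - a[:, None]) / b[:, None]
    return out[0] if was_1d else out


def sg_smooth(spectra, window: int = 11, polyorder: int = 2):
    """Savitzky-Golay smoothing: centered local polynomial least squares.

    Each point is replaced by the value at that point of the degree-
    ``polyorder`` polynomial fitted over its centered ``window``; at the
    edges the polynomial fitted to the nearest full window is evaluated.
    """
    x, was_1d = _rows(spectra)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be below window")
    if window > x.shape[1]:
        raise ValueError("window exceeds the spectrum length")
    out = savgol_filter(x, window_length=window, polyorder=polyorder, axis=-1, mode="interp")
    return out[0] if was_1d else out


def preprocess(
    spectra: SpectrumSet,
    config: PreprocessConfig,
    msc_reference: np.ndarray | None = None,
) -> tuple:
    """Apply the configured pretreatment to a :class:`SpectrumSet`.

    Returns ``(processed SpectrumSet, info dict)``; for MSC the info dict
    carries the reference spectrum actually used, so a training-set
    reference can be reused for test spectra:

    >>> train_p, info = preprocess(train, cfg)            # doctest: +SKIP
    >>> test_p, _ = preprocess(test, cfg, info["msc_reference"])  # doctest: +SKIP
    """
    method = config.method.lower()
    info: dict = {"method": method}
    if method == "none":
        out = spectra.spectra.copy()
    elif method == "snv":
        out = snv(spectra.spectra)
    elif method == "sg":
        out = sg_smooth(spectra.spectra, config.sg_window, config.sg_polyorder)
    elif method == "msc":
        if msc_reference is None and not isinstance(config.msc_reference, str):
            msc_reference = np.asarray(config.msc_reference, dtype=float)
        if msc_reference is None:
            msc_reference = spectra.spectra.mean(axis=0)
        out = msc(spectra.spectra, msc_reference)
        info["msc_reference"] = np.asarray(msc_reference, dtype=float)
    else:  # pragma: no cover - guarded by PreprocessConfig
        raise ValueError(method)
    return spectra.with_spectra(out), info
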