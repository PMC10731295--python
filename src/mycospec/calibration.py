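"""Black/white correction of raw cubes, band cropping, and ROI spectra.

A raw micro-hyperspectral cube holds sensor counts I_raw(x, y, lambda).
Transmittance is recovered against a bright reference frame (an image of
uninoculated medium) and a dark-current frame:

    R = (I_raw - I_dark) / (I_ref - I_dark)

Downstream analysis works on mean transmittance spectra over a mycelium
region-of-interest mask, restricted to the effective band window (the
reddest detector bands are noise-dominated and dropped).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawCube",
    "ReferencePair",
    "TransmittanceCube",
    "SpectrumSet",
    "CalibrationError",
    "calibrate",
    "crop_bands",
    "default_crop",
    "roi_mean_spectrum",
    "spectra_from_samples",
    "DEFAULT_CROP_LOW_NM",
    "DEFAULT_CROP_N_BANDS",
]

#: Nominal lower edge of the effective analysis window (nm).
DEFAULT_CROP_LOW_NM = 400.0
#: Number of bands retained by the default crop (the reddest detector
#: bands beyond this count are noise-dominated and discarded).
DEFAULT_CROP_N_BANDS = 336


class CalibrationError(ValueError):
    """Raised when reference frames cannot calibrate a cube."""


def _as_band_axis(wavelengths_nm) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.ndim != 1 or wl.size < 1:
        raise ValueError("wavelength axis must be a 1-D vector")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength axis must be strictly increasing")
    return wl


@dataclasses.dataclass
class RawCube:
    """Uncorrected intensity cube, H x W x B sensor counts."""

    intensities: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavelengths_nm = _as_band_axis(self.wavelengths_nm)
        if self.intensities.ndim != 3:
            raise ValueError("cube must be H x W x B")
        if self.intensities.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"cube has {self.intensities.shape[2]} bands but the "
                f"wavelength axis has {self.wavelengths_nm.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("cube contains non-finite intensities")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclasses.dataclass
class ReferencePair:
    """Per-pixel-per-band bright (white) and dark reference frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim != 3:
            raise ValueError("reference frames must be H x W x B")


@dataclasses.dataclass
class TransmittanceCube:
    """Calibrated dimensionless transmittance cube.

    Values are floored at zero; they may exceed 1 where the specimen is
    brighter than the reference (``calibrate`` applies a configurable
    ceiling).
    """

    transmittance: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        self.wavelengths_nm = _as_band_axis(self.wavelengths_nm)
        if self.transmittance.ndim != 3:
            raise ValueError("cube must be H x W x B")
        if self.transmittance.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band count does not match the wavelength axis")

    @property
    def shape(self) -> tuple:
        return self.transmittance.shape


@dataclasses.dataclass
class SpectrumSet:
    """Mean ROI transmittance spectra: n_samples x n_bands, with labels."""

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        # band columns may be reordered (e.g. SPA chain order), so the
        # wavelength axis is not required to be monotone here
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelength axis must be a 1-D vector")
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n, b = self.spectra.shape
        if b != self.wavelengths_nm.size:
            raise ValueError("spectra width does not match the wavelength axis")
        if self.labels.shape != (n,) or self.sample_ids.shape != (n,):
            raise ValueError("labels/sample_ids must have one entry per row")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def subset_rows(self, index) -> "SpectrumSet":
        index = np.asarray(index)
        return SpectrumSet(
            self.spectra[index],
            self.wavelengths_nm.copy(),
            self.labels[index],
            self.sample_ids[index],
        )

    def subset_bands(self, band_index: Sequence[int]) -> "SpectrumSet":
        band_index = np.asarray(band_index, dtype=int)
        return SpectrumSet(
            self.spectra[:, band_index],
            self.wavelengths_nm[band_index],
            self.labels.copy(),
            self.sample_ids.copy(),
        )

    def rows_for_ids(self, ids: Iterable[str]) -> np.ndarray:
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        return np.array([pos[i] for i in ids], dtype=int)

    def with_spectra(self, spectra: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(
            spectra, self.wavelengths_nm.copy(), self.labels.copy(), self.sample_ids.copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{w:.4f}" for w in self.wavelengths_nm]
        df = pd.DataFrame(self.spectra, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectrumSet":
        wl = np.array([float(c) for c in df.columns[2:]])
        return cls(
            df.iloc[:, 2:].to_numpy(dtype=float),
            wl,
            df["label"].to_numpy(dtype=int),
            df["id"].to_numpy(dtype=object),
        )


def calibrate(
    raw: RawCube,
    refs: ReferencePair,
    epsilon: float = 1e-6,
    clip_max: float = 2.0,
    max_degenerate_frac: float = 0.01,
) -> TransmittanceCube:
    """Black/white-correct a raw cube to transmittance.

    ``R = (I_raw - I_dark) / (I_ref - I_dark)`` elementwise. Cells whose
    denominator has magnitude below ``epsilon`` are set to 0; if more than
    ``max_degenerate_frac`` of all cells are degenerate the reference pair
    is rejected. The result is clipped to ``[0, clip_max]``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if refs.white.shape != raw.intensities.shape:
        raise ValueError(
            f"reference shape {refs.white.shape} does not match cube shape "
            f"{raw.intensities.shape}"
        )
    denom = refs.white - refs.dark
    degenerate = np.abs(denom) < epsilon
    n_bad = int(degenerate.sum())
    if n_bad > max_degenerate_frac * denom.size:
        raise CalibrationError(
            f"{n_bad} of {denom.size} pixel-bands have |white - dark| < "
            f"{epsilon}; the reference pair is unusable"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (raw.intensities - refs.dark) / denom
    if n_bad:
        r[degenerate] = 0.0
    np.clip(r, 0.0, clip_max, out=r)
    return TransmittanceCube(r, raw.wavelengths_nm.copy())


def crop_bands(obj, low_nm: float, high_nm: float):
    """Keep bands with ``low_nm <= lambda <= high_nm`` (inclusive).

    Works on a :class:`TransmittanceCube` or a :class:`SpectrumSet` and
    returns the same kind.
    """
    if not low_nm < high_nm:
        raise ValueError("low_nm must be below high_nm")
    wl = obj.wavelengths_nm
    keep = np.flatnonzero((wl >= low_nm) & (wl <= high_nm))
    if keep.size < 2:
        raise ValueError(
            f"window [{low_nm}, {high_nm}] nm contains {keep.size} band(s); "
            "at least 2 are required"
        )
    return _take_bands(obj, keep)


def default_crop(
    obj,
    low_nm: float = DEFAULT_CROP_LOW_NM,
    n_bands: int | None = DEFAULT_CROP_N_BANDS,
):
    """Apply the default analysis-window crop.

    Keeps ``n_bands`` bands starting at the first band at or above
    ``low_nm`` — i.e. discards the noise-dominated reddest bands by count
    (24 of 360 on the default axis, leaving 336 bands from roughly 400 to
    1000 nm). ``n_bands=None`` keeps everything above ``low_nm``.
    """
    wl = obj.wavelengths_nm
    above = np.flatnonzero(wl >= low_nm)
    if above.size < 2:
        raise ValueError(f"fewer than 2 bands at or above {low_nm} nm")
    start = int(above[0])
    stop = wl.size if n_bands is None else min(wl.size, start + int(n_bands))
    keep = np.arange(start, stop)
    if keep.size < 2:
        raise ValueError("default crop would keep fewer than 2 bands")
    return _take_bands(obj, keep)


def _take_bands(obj, keep: np.ndarray):
    if isinstance(obj, TransmittanceCube):
        return TransmittanceCube(obj.transmittance[:, :, keep], obj.wavelengths_nm[keep])
    if isinstance(obj, SpectrumSet):
        return obj.subset_bands(keep)
    if isinstance(obj, RawCube):
        return RawCube(obj.intensities[:, :, keep], obj.wavelengths_nm[keep])
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")


def roi_mean_spectrum(cube: TransmittanceCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the cube over the ROI mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match the cube's spatial shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return cube.transmittance[mask].mean(axis=0)


def spectra_from_samples(
    samples,
    epsilon: float = 1e-6,
    clip_max: float = 2.0,
    crop_low_nm: float = DEFAULT_CROP_LOW_NM,
    crop_n_bands: int | None = DEFAULT_CROP_N_BANDS,
) -> SpectrumSet:
    """Calibrate, crop, and reduce samples to a :class:`SpectrumSet`.

    ``samples`` is an iterable of ``(sample_id, SyntheticSample)`` pairs or
    of ``SyntheticSample`` objects (ids are then generated as ``s0000``...).
    """
    rows, labels, ids = [], [], []
    wl = None
    for i, item in enumerate(samples):
        if isinstance(item, tuple):
            sid, sample = item
        else:
            sid, sample = f"s{i:04d}", item
        cube = calibrate(sample.raw_cube, sample.references, epsilon=epsilon, clip_max=clip_max)
        cube = default_crop(cube, low_nm=crop_low_nm, n_bands=crop_n_bands)
        rows.append(roi_mean_spectrum(cube, sample.roi_mask))
        labels.append(sample.label)
        ids.append(sid)
        wl = cube.wavelengths_nm
    if not rows:
        raise ValueError("no samples supplied")
    return SpectrumSet(np.vstack(rows), wl, np.array(labels), np.array(ids, dtype=object))
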