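"""Seeded synthetic micro-hyperspectral scenes of fungal mycelium.

The generator emulates transmittance-mode micro-hyperspectral imaging of
*Pleurotus* mycelium at four ordinal degradation grades (labels 0-3):

* filaments are smooth jointed random-walk curves rasterized with a
  Gaussian cross-profile whose width *decreases* with degradation grade;
* mycelium transmittance *increases* slightly with grade (degraded
  filaments are more translucent);
* all grades share one smooth peak/valley endmember structure, so the
  class spectra have similar trends and differ subtly;
* raw counts are ``dark + T * (white - dark)`` plus Gaussian sensor
  noise, where the bright reference emulates an image of uninoculated
  medium (smooth spatial gain and spectral illumination tilt);
* each sample carries a per-sample multiplicative scatter slope and an
  additive baseline drift — exactly the distortion family that SNV/MSC
  correct.

All randomness flows from explicit seeds; no global random state is used.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import RawCube, ReferencePair

__all__ = [
    "ConfigurationError",
    "ClassProfile",
    "SceneConfig",
    "SyntheticSample",
    "default_endmembers",
    "default_scene_config",
    "generate_sample",
    "generate_dataset",
    "iter_dataset",
    "dataset_manifest",
]

# Class-profile defaults: filament width (mean px, sd px) strictly
# decreases with grade; mycelium transmittance offset strictly increases.
# Widths separate grades 0|1 and 2|3 sharply but 1|2 weakly; the
# mycelium peak/valley shapes do the opposite (0|1 and 2|3 nearly share
# a shape, 1|2 differ), so the spectral and image channels carry
# complementary class information.
_DEFAULT_WIDTHS = ((12.0, 1.2), (8.0, 1.0), (7.4, 1.0), (4.5, 0.8))
_DEFAULT_OFFSETS = (0.0, 0.006, 0.035, 0.042)
_DEFAULT_SHAPE_WEIGHTS = (0.0, 0.07, 0.55, 0.62)  # scales the shape modulation
_WIDTH_ANCHOR = 8.0  # contrast scaling pivots class widths around this mean


class ConfigurationError(ValueError):
    """Raised for inconsistent scene configurations."""


@dataclasses.dataclass(frozen=True)
class ClassProfile:
    """One degradation grade: filament geometry plus endmember spectra."""

    label: int
    filament_width_px: tuple  # (mean, sd)
    transmittance_offset: float
    endmember_mycelium: np.ndarray
    endmember_background: np.ndarray


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Full description of the synthetic imaging conditions."""

    classes: tuple
    image_height: int = 128
    image_width: int = 128
    n_bands: int = 360
    wavelength_start_nm: float = 401.0
    wavelength_end_nm: float = 1046.0
    filaments_per_image: tuple = (3, 6)
    noise_sd: float = 0.008
    baseline_drift_sd: float = 0.02
    scatter_slope_sd: float = 0.05
    endmember_variability: float = 0.01
    white_level: float = 3000.0
    dark_level: float = 96.0
    reference_variation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be at least 2")
        if not self.wavelength_start_nm < self.wavelength_end_nm:
            raise ConfigurationError("wavelength range must be increasing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.endmember_variability < 0:
            raise ConfigurationError("endmember_variability must be non-negative")
        if not self.classes:
            raise ConfigurationError("at least one class profile is required")
        labels = [p.label for p in self.classes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("class labels must be distinct")
        ordered = sorted(self.classes, key=lambda p: p.label)
        widths = [p.filament_width_px[0] for p in ordered]
        offsets = [p.transmittance_offset for p in ordered]
        if any(b >= a for a, b in zip(widths, widths[1:])):
            raise ConfigurationError("filament width must strictly decrease with label")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ConfigurationError("transmittance offset must strictly increase with label")
        for p in self.classes:
            for curve in (p.endmember_mycelium, p.endmember_background):
                curve = np.asarray(curve, dtype=float)
                if curve.shape != (self.n_bands,):
                    raise ConfigurationError("endmember length must equal n_bands")
                if curve.min() <= 0 or curve.max() > 1.2:
                    raise ConfigurationError("endmember curves must lie in (0, 1.2]")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        # evenly spaced at (end - start) / (n_bands - 1)
        return np.linspace(self.wavelength_start_nm, self.wavelength_end_nm, self.n_bands)

    def profile_for(self, label: int) -> ClassProfile:
        for p in self.classes:
            if p.label == label:
                return p
        raise ConfigurationError(f"label {label} is not configured")


@dataclasses.dataclass
class SyntheticSample:
    """One generated cube with its references, ROI, and ground truth."""

    raw_cube: RawCube
    references: ReferencePair
    roi_mask: np.ndarray
    label: int
    transmittance: np.ndarray  # the encoded field, after per-sample distortion
    truth: dict

    @property
    def white_frame(self) -> np.ndarray:
        return self.references.white

    @property
    def dark_frame(self) -> np.ndarray:
        return self.references.dark


def _smooth_bumps(t: np.ndarray, centers, widths, amps) -> np.ndarray:
    y = np.zeros_like(t)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return y


def default_endmembers(n_bands: int, shape_weight: float = 0.0) -> tuple:
    """Smooth transmittance curves (mycelium, background) for one grade.

    All grades share a gently sloped baseline with the same Gaussian
    peak/valley positions, so class spectra have similar trends.
    ``shape_weight`` scales a small mean-free modulation of the mycelium
    peak/valley amplitudes: degraded mycelium changes composition, so
    its peaks and valleys deepen subtly while the overall trend is kept.
    """
    t = np.linspace(0.0, 1.0, n_bands)
    background = 0.90 - 0.05 * t + _smooth_bumps(
        t, (0.25, 0.70), (0.12, 0.18), (0.04, -0.05)
    )
    mycelium = 0.42 + 0.10 * t + _smooth_bumps(
        t,
        (0.12, 0.38, 0.62, 0.85),
        (0.05, 0.08, 0.07, 0.06),
        (0.06, -0.08, 0.05, -0.06),
    )
    if shape_weight:
        mycelium = mycelium + shape_weight * _smooth_bumps(
            t, (0.20, 0.50, 0.78), (0.06, 0.07, 0.05), (0.03, -0.03, 0.03)
        )
    return np.clip(mycelium, 0.01, 1.2), np.clip(background, 0.01, 1.2)


def default_scene_config(
    n_bands: int = 360,
    image_size: int = 128,
    class_contrast: float = 1.0,
    **overrides,
) -> SceneConfig:
    """Build the default four-grade scene.

    ``class_contrast`` scales the between-class differences (widths pivot
    around their anchor mean, offsets scale toward 0); ``0`` yields
    classes that are statistically indistinguishable (a vanishing ordered
    residual keeps the monotone encoding well defined), for null
    experiments.
    """
    if class_contrast < 0:
        raise ConfigurationError("class_contrast must be non-negative")
    profiles = []
    for label in range(4):
        myc, bg = default_endmembers(
            n_bands, shape_weight=class_contrast * _DEFAULT_SHAPE_WEIGHTS[label]
        )
        w_mean, w_sd = _DEFAULT_WIDTHS[label]
        w = _WIDTH_ANCHOR + class_contrast * (w_mean - _WIDTH_ANCHOR) - 1e-9 * label
        off = class_contrast * _DEFAULT_OFFSETS[label] + 1e-12 * label
        profiles.append(
            ClassProfile(
                label=label,
                filament_width_px=(w, w_sd),
                transmittance_offset=off,
                endmember_mycelium=myc,
                endmember_background=bg,
            )
        )
    return SceneConfig(
        classes=tuple(profiles),
        image_height=image_size,
        image_width=image_size,
        n_bands=n_bands,
        **overrides,
    )


def _smooth_field(rng: np.random.Generator, shape: tuple, n_knots: int = 5) -> np.ndarray:
    """Smooth random spatial field, roughly unit amplitude."""
    coarse = rng.normal(size=(n_knots, n_knots))
    f = ndimage.zoom(
        coarse,
        (shape[0] / n_knots, shape[1] / n_knots),
        order=3,
        mode="nearest",
        grid_mode=True,
    )[: shape[0], : shape[1]]
    peak = max(float(np.abs(f).max()), 1e-12)
    return f / peak


def _filament_coverage(
    rng: np.random.Generator, height: int, width_px: float, width: int
) -> np.ndarray:
    """Rasterize one jointed random-walk filament with Gaussian profile."""
    h, w = height, width
    start = np.array([rng.uniform(2, h - 2), rng.uniform(2, w - 2)])
    ang0 = rng.uniform(0.0, 2.0 * np.pi)
    mask = np.zeros((h, w), dtype=bool)
    max_steps = 2 * (h + w)
    for direction in (0.0, np.pi):  # grow both ways from the start point
        pos = start.copy()
        ang = ang0 + direction
        for _ in range(max_steps):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w):
                break
            mask[r, c] = True
            ang += rng.normal(0.0, 0.18)
            pos += np.array([np.sin(ang), np.cos(ang)])
    if not mask.any():
        mask[int(round(start[0])), int(round(start[1]))] = True
    dist = ndimage.distance_transform_edt(~mask)
    sigma = max(float(width_px), 1.0) / 2.3548  # FWHM -> sigma
    return np.exp(-0.5 * (dist / sigma) ** 2)


def generate_sample(config: SceneConfig, label: int, seed: int) -> SyntheticSample:
    """Generate one seeded cube + references + ROI for the given grade."""
    profile = config.profile_for(label)
    rng = np.random.default_rng(seed)
    h, w, b = config.image_height, config.image_width, config.n_bands
    wl = config.wavelengths_nm

    # Reference frames: smooth spectral illumination tilt and spatial gain,
    # scaled by reference_variation (0 -> perfectly flat references). The
    # dark frame is spectrally flat, so it is stored as a broadcast view.
    t = np.linspace(0.0, 1.0, b)
    spectral_shape = 0.5 * np.cos(np.pi * t)
    rv = config.reference_variation
    f_white = _smooth_field(rng, (h, w))
    f_dark = _smooth_field(rng, (h, w))
    if rv > 0:
        white = 0.6 * spectral_shape[None, None, :] + 0.4 * f_white[:, :, None]
        white *= config.white_level * rv
        white += config.white_level
        dark_hw1 = config.dark_level * (1.0 + 0.5 * rv * f_dark[:, :, None])
    else:
        white = np.broadcast_to(np.float64(config.white_level), (h, w, b))
        dark_hw1 = np.full((h, w, 1), float(config.dark_level))
    dark = np.broadcast_to(dark_hw1, (h, w, b))
    if np.any(white <= dark_hw1):
        raise ConfigurationError("white frame must exceed dark frame everywhere")

    # Filament coverage field.
    lo, hi = config.filaments_per_image
    n_fil = int(rng.integers(int(lo), int(hi) + 1))
    coverage = np.zeros((h, w))
    widths = []
    for _ in range(n_fil):
        fil_width = max(1.5, rng.normal(*profile.filament_width_px))
        widths.append(fil_width)
        coverage = np.maximum(coverage, _filament_coverage(rng, h, fil_width, w))

    # Transmittance field: linear endmember blend + per-sample distortion.
    # Each sample carries its own smooth biological deviation of the
    # mycelium curve (shared by all pixels), so replicates of one grade
    # are not spectrally identical.
    myc = np.clip(profile.endmember_mycelium + profile.transmittance_offset, 1e-6, 1.2)
    if config.endmember_variability > 0:
        tb = np.linspace(0.0, 1.0, b)
        amps = rng.normal(0.0, config.endmember_variability, size=4)
        myc = np.clip(
            myc + _smooth_bumps(tb, (0.15, 0.40, 0.65, 0.90), (0.08, 0.08, 0.08, 0.08), amps),
            1e-6,
            1.2,
        )
    transmittance = coverage[:, :, None] * myc[None, None, :]
    transmittance += (1.0 - coverage)[:, :, None] * profile.endmember_background[None, None, :]
    slope = 1.0 + rng.normal(0.0, config.scatter_slope_sd)
    baseline = rng.normal(0.0, config.baseline_drift_sd)
    transmittance *= slope
    transmittance += baseline

    gain = white - dark_hw1
    if config.noise_sd > 0:
        raw = transmittance + rng.normal(0.0, config.noise_sd, size=transmittance.shape)
        raw *= gain
    else:
        raw = transmittance * gain
    raw += dark_hw1

    roi_mask = coverage > 0.5
    min_pixels = 50
    if roi_mask.sum() < min_pixels:
        # fall back to the highest-coverage (filament-core) pixels
        flat = np.argpartition(coverage.ravel(), -min_pixels)[-min_pixels:]
        roi_mask = np.zeros((h, w), dtype=bool)
        roi_mask.ravel()[flat] = True

    truth = {
        "label": label,
        "filament_widths_px": widths,
        "n_filaments": n_fil,
        "scatter_slope": slope,
        "baseline_offset": baseline,
        "transmittance_offset": profile.transmittance_offset,
        "seed": int(seed),
    }
    return SyntheticSample(
        raw_cube=RawCube(raw, wl),
        references=ReferencePair(white, dark),
        roi_mask=roi_mask,
        label=label,
        transmittance=transmittance,
        truth=truth,
    )


def _sample_seeds(master_seed: int, n: int) -> np.ndarray:
    seeds = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint32)
    return (seeds & 0x7FFFFFFF).astype(np.int64)


def dataset_manifest(config: SceneConfig, n_per_class: int, seed: int | None = None) -> pd.DataFrame:
    """Deterministic manifest (id, label, seed) for a balanced dataset."""
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be at least 1")
    master = config.seed if seed is None else seed
    labels = sorted(p.label for p in config.classes)
    seeds = _sample_seeds(master, len(labels) * n_per_class)
    rows = []
    i = 0
    for label in labels:
        for _ in range(n_per_class):
            rows.append((f"s{i:04d}", label, int(seeds[i])))
            i += 1
    return pd.DataFrame(rows, columns=["id", "label", "seed"])


def iter_dataset(
    config: SceneConfig, n_per_class: int, seed: int | None = None
) -> Iterator[tuple]:
    """Yield ``(sample_id, SyntheticSample)`` pairs without holding all cubes."""
    manifest = dataset_manifest(config, n_per_class, seed)
    for row in manifest.itertuples(index=False):
        yield row.id, generate_sample(config, int(row.label), int(row.seed))


def generate_dataset(
    config: SceneConfig, n_per_class: int, seed: int | None = None
) -> tuple:
    """Balanced dataset: list of samples plus a manifest table."""
    manifest = dataset_manifest(config, n_per_class, seed)
    samples = [
        generate_sample(config, int(row.label), int(row.seed))
        for row in manifest.itertuples(index=False)
    ]
    return samples, manifest
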