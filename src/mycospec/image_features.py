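"""Per-sample image feature vectors from grayscale band images.

Each sample contributes one grayscale image per selected wavelength; the
images are center-cropped, bilinearly resized, min-max normalized,
replicated to three channels, and pushed through a convolutional feature
backend to a fixed-width vector (2048-d by default). Per-band vectors are
aggregated (mean by default) into one feature vector per sample.

Backends
--------
``seeded-conv`` (default)
    A fixed-architecture convolutional stack with seeded random weights
    and adaptive average pooling. Random convolutional features are an
    established texture descriptor: no training, no downloads, fully
    deterministic for a given seed.
``resnet50-pretrained``
    The transfer-learning pathway (pre-FC pooled activations of a
    pretrained ResNet50). Requires ``torch``/``torchvision``; when they
    are absent a :class:`BackendUnavailableError` points back to the
    seeded backend.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .calibration import TransmittanceCube

__all__ = [
    "BandImageStack",
    "FeatureMatrix",
    "BackendUnavailableError",
    "SeededConvBackend",
    "PretrainedResNet50Backend",
    "get_backend",
    "prepare_image",
    "extract_features",
    "band_images_from_cube",
]


class BackendUnavailableError(RuntimeError):
    """Raised when an optional feature backend cannot be constructed."""


@dataclasses.dataclass
class BandImageStack:
    """Grayscale band images: n_samples x n_bands x H x W."""

    images: np.ndarray
    band_wavelengths_nm: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must be n_samples x n_bands x H x W")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("band images contain non-finite values")
        self.band_wavelengths_nm = np.asarray(self.band_wavelengths_nm, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        n, k = self.images.shape[:2]
        if self.band_wavelengths_nm.size != k:
            raise ValueError("one wavelength per band image is required")
        if self.sample_ids.size != n or self.labels.size != n:
            raise ValueError("ids/labels must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]


@dataclasses.dataclass
class FeatureMatrix:
    """n_samples x feature_dim image-derived features, row-aligned with ids."""

    features: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        n = self.features.shape[0]
        if self.sample_ids.size != n or self.labels.size != n:
            raise ValueError("ids/labels must have one entry per row")

    def rows_for_ids(self, ids) -> np.ndarray:
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        return np.array([pos[i] for i in ids], dtype=int)


def _bilinear_resize_square(image: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize of a square image, pixel-center coordinate mapping."""
    scale = image.shape[0] / out_size
    coords = (np.arange(out_size) + 0.5) * scale - 0.5
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    return ndimage.map_coordinates(image, [rr, cc], order=1, mode="nearest")


def prepare_image(image: np.ndarray, out_size: int = 224) -> np.ndarray:
    """Crop, resize, normalize, and replicate one band image to 3 channels.

    Center-crops to the largest centered square, resizes to
    ``out_size x out_size`` with bilinear interpolation, min-max
    normalizes to [0, 1] per image (a constant image maps to all zeros),
    and stacks three identical channels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    h, w = img.shape
    if h < 8 or w < 8:
        raise ValueError("image must be at least 8 x 8")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    crop = img[r0 : r0 + side, c0 : c0 + side]
    resized = crop.astype(float).copy() if side == out_size else _bilinear_resize_square(crop, out_size)
    lo, hi = float(resized.min()), float(resized.max())
    if hi > lo:
        resized = (resized - lo) / (hi - lo)
    else:
        resized = np.zeros_like(resized)
    return np.stack([resized, resized, resized])


def _conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution, (C,H,W) -> (O,H,W), via im2col matmul."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    windows = sliding_window_view(xp, (3, 3), axis=(1, 2))  # C,H,W,3,3
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)
    out = cols @ weight.reshape(weight.shape[0], -1).T + bias
    return out.T.reshape(weight.shape[0], h, w)


def _mean_pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    x = x[:, :h2, :w2]
    return x.reshape(c, h2 // 2, 2, w2 // 2, 2).mean(axis=(2, 4))


class SeededConvBackend:
    """Deterministic random-convolution texture features.

    Three 3x3 convolution stages (channels 3 -> 16 -> 32 -> 128) with
    modulus nonlinearity and 2x2 mean pooling between stages. Filament
    position is irrelevant for grading, so each stage is reduced to
    translation-invariant channel statistics (global mean and standard
    deviation of every response map, 352 values), which a fixed seeded
    linear map lifts to the ``feature_dim``-wide output. All weights are
    drawn once from a dedicated seeded generator; the same input always
    yields the same output and there is no cross-sample state.
    """

    name = "seeded-conv"
    deterministic = True

    _CHANNELS = (3, 16, 32, 128)

    def __init__(self, seed: int = 0, feature_dim: int = 2048) -> None:
        if feature_dim < 1:
            raise ValueError("feature_dim must be positive")
        self.seed = int(seed)
        self.feature_dim = int(feature_dim)
        rng = np.random.default_rng(self.seed)
        self._weights = []
        for c_in, c_out in zip(self._CHANNELS, self._CHANNELS[1:]):
            scale = np.sqrt(2.0 / (c_in * 9))
            self._weights.append(rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)))
        n_stats = 2 * sum(self._CHANNELS[1:])
        self._lift = rng.normal(0.0, 1.0 / np.sqrt(n_stats), size=(n_stats, feature_dim))

    def __call__(self, prepared: np.ndarray) -> np.ndarray:
        x = np.asarray(prepared, dtype=float)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError("backend input must be (3, S, S)")
        if min(x.shape[1:]) < 16:
            raise ValueError("backend input must be at least 16 x 16")
        zero_bias = np.zeros(max(self._CHANNELS))
        stats = []
        for i, w in enumerate(self._weights):
            x = np.abs(_conv3x3(x, w, zero_bias[: w.shape[0]]))
            stats.append(x.mean(axis=(1, 2)))
            stats.append(x.std(axis=(1, 2)))
            if i < len(self._weights) - 1:
                x = _mean_pool2(x)
        return np.concatenate(stats) @ self._lift


class PretrainedResNet50Backend:
    """Pretrained ResNet50 pooled activations (optional, needs torch)."""

    name = "resnet50-pretrained"
    deterministic = True
    feature_dim = 2048

    def __init__(self) -> None:
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "the resnet50-pretrained backend requires torch and "
                "torchvision with downloaded weights; use the default "
                "'seeded-conv' backend instead"
            ) from exc
        import torch
        from torchvision.models import ResNet50_Weights, resnet50

        model = resnet50(weights=ResNet50_Weights.IMAGENET1K_V2)
        model.fc = torch.nn.Identity()
        model.eval()
        self._model = model
        self._torch = torch

    def __call__(self, prepared: np.ndarray) -> np.ndarray:
        with self._torch.no_grad():
            t = self._torch.as_tensor(prepared[None], dtype=self._torch.float32)
            return self._model(t).numpy().ravel()


def get_backend(name: str = "seeded-conv", seed: int = 0, feature_dim: int = 2048):
    if name == "seeded-conv":
        return SeededConvBackend(seed=seed, feature_dim=feature_dim)
    if name in ("resnet50", "resnet50-pretrained"):
        return PretrainedResNet50Backend()
    raise ValueError(f"unknown backend {name!r}")


def band_images_from_cube(cube: TransmittanceCube, band_indices) -> np.ndarray:
    """Grayscale images (k, H, W) at the selected band indices."""
    idx = np.asarray(band_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= cube.shape[2]):
        raise IndexError("band index out of range")
    return np.moveaxis(cube.transmittance[:, :, idx], -1, 0)


def extract_features(
    stack: BandImageStack,
    backend,
    aggregate: str = "mean",
    out_size: int = 224,
) -> FeatureMatrix:
    """Backend features for every sample, aggregated across band images."""
    if stack.n_samples == 0:
        raise ValueError("empty band image stack")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    rows = []
    for s in range(stack.n_samples):
        per_band = np.stack(
            [backend(prepare_image(img, out_size=out_size)) for img in stack.images[s]]
        )
        rows.append(per_band.mean(axis=0) if aggregate == "mean" else per_band.max(axis=0))
    return FeatureMatrix(np.vstack(rows), stack.sample_ids.copy(), stack.labels.copy())
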