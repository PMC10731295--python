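"""File formats: ENVI cubes, mask images, spectrum CSV, selection JSON,
and a fused-model archive.

ENVI support covers the plain-text ``.hdr`` + flat-binary layout in its
three interleaves (BSQ, BIL, BIP) with byte order and data type taken
from the header. Masks are single-band 8-bit images (nonzero = ROI).
The model archive stores the kernel configuration together with the
standardized training feature blocks and labels; loading refits the
(deterministic) dual solver, which reproduces the identical model.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .band_selection import BandSelection
from .calibration import RawCube, SpectrumSet, TransmittanceCube
from .fusion_svm import FusedKernelModel, KernelConfig, fit, fuse, rbf_gram

__all__ = [
    "write_envi",
    "read_envi",
    "write_dataset",
    "write_mask",
    "read_mask",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_band_selection",
    "read_band_selection",
    "save_model",
    "load_model",
]

_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def write_envi(cube, path_base, interleave: str = "bsq", dtype=np.float32) -> Path:
    """Write a cube as ENVI ``<base>.hdr`` + ``<base>.raw`` (little-endian).

    ``cube`` is a :class:`RawCube` or :class:`TransmittanceCube`; returns
    the header path.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError("interleave must be bsq, bil, or bip")
    data = cube.intensities if isinstance(cube, RawCube) else cube.transmittance
    dtype = np.dtype(dtype)
    if dtype not in _CODE_FOR_DTYPE:
        raise ValueError(f"unsupported dtype {dtype}")
    h, w, b = data.shape
    if interleave == "bsq":
        ordered = np.transpose(data, (2, 0, 1))  # bands, lines, samples
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))  # lines, bands, samples
    else:
        ordered = data  # lines, samples, bands
    base = Path(path_base)
    raw_path = base.with_suffix(".raw")
    hdr_path = base.with_suffix(".hdr")
    ordered.astype(dtype.newbyteorder("<")).tofile(raw_path)
    wl = ", ".join(f"{x:.4f}" for x in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        "description = {mycospec synthetic micro-hyperspectral cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR_DTYPE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    return hdr_path


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    # join brace-delimited multiline values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(hdr_path) -> TransmittanceCube | RawCube:
    """Read an ENVI cube; returns a :class:`RawCube` (intensity semantics).

    Wavelengths come from the header's ``wavelength`` block when present,
    else a unit band index axis is used.
    """
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    w = int(fields["samples"])
    h = int(fields["lines"])
    b = int(fields["bands"])
    code = int(fields.get("data type", 4))
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    order = "<" if int(fields.get("byte order", 0)) == 0 else ">"
    dtype = np.dtype(_DTYPE_CODES[code]).newbyteorder(order)
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        candidates = [p for p in hdr_path.parent.glob(hdr_path.stem + ".*") if p != hdr_path]
        if not candidates:
            raise FileNotFoundError(f"no binary companion for {hdr_path}")
        raw_path = candidates[0]
    flat = np.fromfile(raw_path, dtype=dtype, offset=offset, count=h * w * b)
    if flat.size != h * w * b:
        raise ValueError(f"{raw_path} holds {flat.size} values, expected {h * w * b}")
    if interleave == "bsq":
        data = flat.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(h, w, b)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if "wavelength" in fields:
        wl = np.array(
            [float(x) for x in fields["wavelength"].strip("{} ").split(",") if x.strip()]
        )
    else:
        wl = np.arange(b, dtype=float)
    return RawCube(np.ascontiguousarray(data, dtype=float), wl)


def write_dataset(samples, manifest: pd.DataFrame, directory, interleave: str = "bsq") -> Path:
    """Write a generated dataset to disk: ENVI cubes + masks + manifest.

    Each sample gets ``<id>.hdr/.raw`` (the raw cube), ``<id>_white`` and
    ``<id>_dark`` reference cubes, and ``<id>_mask.png``; the manifest CSV
    (columns id, label, seed, path) points at the cube headers. Returns
    the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, row in zip(samples, manifest.itertuples(index=False)):
        base = directory / row.id
        hdr = write_envi(sample.raw_cube, base, interleave=interleave)
        wl = sample.raw_cube.wavelengths_nm
        write_envi(RawCube(sample.white_frame, wl), directory / f"{row.id}_white", interleave)
        write_envi(RawCube(sample.dark_frame, wl), directory / f"{row.id}_dark", interleave)
        write_mask(sample.roi_mask, directory / f"{row.id}_mask.png")
        paths.append(str(hdr))
    out = manifest.copy()
    out["path"] = paths
    manifest_path = directory / "manifest.csv"
    out.to_csv(manifest_path, index=False)
    return manifest_path


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean ROI mask as an 8-bit single-band image (255 = ROI)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_spectra_csv(spectra: SpectrumSet, path) -> Path:
    path = Path(path)
    spectra.to_dataframe().to_csv(path, index=False)
    return path


def read_spectra_csv(path) -> SpectrumSet:
    return SpectrumSet.from_dataframe(pd.read_csv(Path(path)))


def write_band_selection(selection: BandSelection, path) -> Path:
    path = Path(path)
    payload = {
        "selected_indices": [int(i) for i in selection.selected_indices],
        "selected_wavelengths_nm": [float(w) for w in selection.selected_wavelengths_nm],
        "start_index": int(selection.start_index),
        "n_bands": int(selection.n_bands),
        "rmse_curve": {str(k): float(v) for k, v in selection.rmse_curve.items()},
        "chosen_rmse": float(selection.chosen_rmse),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_band_selection(path) -> BandSelection:
    payload = json.loads(Path(path).read_text())
    return BandSelection(
        selected_indices=list(payload["selected_indices"]),
        selected_wavelengths_nm=list(payload["selected_wavelengths_nm"]),
        start_index=int(payload["start_index"]),
        n_bands=int(payload["n_bands"]),
        rmse_curve={int(k): float(v) for k, v in payload["rmse_curve"].items()},
        chosen_rmse=float(payload["chosen_rmse"]),
    )


def save_model(model: FusedKernelModel, path) -> Path:
    """Archive a fused model (config + training blocks) as a single .npz."""
    path = Path(path)
    cfg = model.config
    meta = {
        "mu": cfg.mu,
        "gamma_s": cfg.gamma_s,
        "gamma_w": cfg.gamma_w,
        "C": cfg.C,
        "standardized": model.spectral_scaler is not None,
    }
    arrays = {
        "train_spectral": model.train_spectral,
        "train_image": model.train_image,
        "labels": np.asarray(model.training_labels),
        "sample_ids": model.training_sample_ids.astype(str),
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.spectral_scaler is not None:
        arrays["spectral_mean"], arrays["spectral_sd"] = model.spectral_scaler
        arrays["image_mean"], arrays["image_sd"] = model.image_scaler
    np.savez_compressed(path, **arrays)
    return path


def load_model(path) -> FusedKernelModel:
    """Rebuild a fused model from an archive by refitting the dual solver.

    The stored feature blocks are already standardized, so the archive
    also restores the scalers used to map new raw features into that
    space.
    """
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = KernelConfig(
            mu=meta["mu"], gamma_s=meta["gamma_s"], gamma_w=meta["gamma_w"], C=meta["C"]
        )
        xs = data["train_spectral"]
        xw = data["train_image"]
        labels = data["labels"]
        ids = data["sample_ids"].astype(object)
        s_scaler = w_scaler = None
        if meta["standardized"]:
            s_scaler = (data["spectral_mean"], data["spectral_sd"])
            w_scaler = (data["image_mean"], data["image_sd"])
    K = fuse(rbf_gram(xs, xs, config.gamma_s), rbf_gram(xw, xw, config.gamma_w), config.mu)
    svc = fit(K, labels, config.C)
    return FusedKernelModel(
        config=config,
        svc=svc,
        train_spectral=xs,
        train_image=xw,
        spectral_scaler=s_scaler,
        image_scaler=w_scaler,
        training_sample_ids=ids,
        training_labels=labels,
    )
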