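"""End-to-end synthetic experiment: generate -> calibrate -> preprocess ->
select bands -> extract image features -> train fused SVM -> evaluate.

The pipeline streams cubes (each sample is generated, calibrated, and
reduced to its spectrum / band images on the fly, twice, from the same
per-sample seeds) so desk-scale datasets never have to fit in memory as
raw cubes.

Model nomenclature mirrors the standard comparison grid:

* ``spectrum_raw``     - untreated full-window spectra, RBF SVM;
* ``spectrum_spa``     - pretreated, SPA-selected spectra, RBF SVM;
* ``image_raw``        - downsampled mean band image pixels, RBF SVM;
* ``image_features``   - convolutional backend features, RBF SVM;
* ``fused``            - convex kernel fusion of ``spectrum_spa`` and
  ``image_features`` (single-modality models are its mu = 1 / mu = 0
  endpoints).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .band_selection import BandSelection, apply_selection, select_bands
from .calibration import (
    DEFAULT_CROP_LOW_NM,
    DEFAULT_CROP_N_BANDS,
    SpectrumSet,
    calibrate,
    default_crop,
    roi_mean_spectrum,
)
from .evaluation import ClassificationReport, SplitIndices, evaluate, ks_split
from .fusion_svm import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    DEFAULT_MU_GRID,
    KernelConfig,
    grid_search,
    predict,
    train_fused,
)
from .image_features import _bilinear_resize_square, get_backend, prepare_image
from .preprocessing import PreprocessConfig, preprocess
from .synthetic import SceneConfig, dataset_manifest, default_scene_config, generate_sample

__all__ = ["PipelineConfig", "ModelResult", "ComparisonResult", "run_pipeline", "run_comparison"]

ALL_MODELS = ("spectrum_raw", "spectrum_spa", "image_raw", "image_features", "fused")
PRETREATMENTS = ("none", "sg", "msc", "snv")


@dataclasses.dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults are desk scale."""

    scene: SceneConfig = dataclasses.field(default_factory=default_scene_config)
    n_per_class: int = 30
    seed: int = 0
    # calibration
    epsilon: float = 1e-6
    clip_max: float = 2.0
    crop_low_nm: float = DEFAULT_CROP_LOW_NM
    crop_n_bands: int | None = DEFAULT_CROP_N_BANDS
    # pretreatment
    pretreat: str = "snv"
    sg_window: int = 11
    sg_polyorder: int = 2
    # band selection
    spa_n_min: int = 2
    spa_n_max: int = 16
    spa_folds: int = 5
    spa_starts: int | None = None  # None = exhaustive start sweep
    # image features
    backend: str = "seeded-conv"
    backend_seed: int = 0
    feature_dim: int = 2048
    out_size: int = 224
    aggregate: str = "mean"
    raw_image_size: int = 32
    # SVM model selection
    mu_grid: tuple = DEFAULT_MU_GRID
    C_grid: tuple = DEFAULT_C_GRID
    gamma_s_grid: tuple = DEFAULT_GAMMA_GRID
    gamma_w_grid: tuple = DEFAULT_GAMMA_GRID
    svm_folds: int = 3
    # partitioning
    ratio: float = 0.8
    stratified: bool = True
    # which models to train
    models: tuple = ALL_MODELS


@dataclasses.dataclass
class ModelResult:
    name: str
    config: KernelConfig
    train_accuracy: float
    test_accuracy: float
    train_report: ClassificationReport
    test_report: ClassificationReport
    test_predictions: np.ndarray
    cv_table: pd.DataFrame


@dataclasses.dataclass
class ComparisonResult:
    manifest: pd.DataFrame
    spectra: SpectrumSet  # cropped, untreated
    split: SplitIndices
    selection: BandSelection | None
    models: dict  # name -> ModelResult
    model_table: pd.DataFrame
    pretreatment_table: pd.DataFrame | None


def _stream_spectra(config: PipelineConfig, manifest: pd.DataFrame) -> SpectrumSet:
    rows, labels, ids = [], [], []
    wl = None
    for row in manifest.itertuples(index=False):
        sample = generate_sample(config.scene, int(row.label), int(row.seed))
        cube = calibrate(
            sample.raw_cube, sample.references, epsilon=config.epsilon, clip_max=config.clip_max
        )
        cube = default_crop(cube, low_nm=config.crop_low_nm, n_bands=config.crop_n_bands)
        rows.append(roi_mean_spectrum(cube, sample.roi_mask))
        labels.append(sample.label)
        ids.append(row.id)
        wl = cube.wavelengths_nm
    return SpectrumSet(np.vstack(rows), wl, np.array(labels), np.array(ids, dtype=object))


def _stream_image_features(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    band_indices: np.ndarray,
    need_backend: bool,
    need_raw: bool,
) -> tuple:
    """Second pass: backend feature rows and/or raw-pixel rows per sample."""
    backend = (
        get_backend(config.backend, seed=config.backend_seed, feature_dim=config.feature_dim)
        if need_backend
        else None
    )
    feat_rows, raw_rows = [], []
    for row in manifest.itertuples(index=False):
        sample = generate_sample(config.scene, int(row.label), int(row.seed))
        cube = calibrate(
            sample.raw_cube, sample.references, epsilon=config.epsilon, clip_max=config.clip_max
        )
        cube = default_crop(cube, low_nm=config.crop_low_nm, n_bands=config.crop_n_bands)
        band_images = np.moveaxis(cube.transmittance[:, :, band_indices], -1, 0)
        if need_backend:
            per_band = np.stack(
                [backend(prepare_image(img, out_size=config.out_size)) for img in band_images]
            )
            feat_rows.append(
                per_band.mean(axis=0) if config.aggregate == "mean" else per_band.max(axis=0)
            )
        if need_raw:
            mean_image = band_images.mean(axis=0)
            side = min(mean_image.shape)
            r0 = (mean_image.shape[0] - side) // 2
            c0 = (mean_image.shape[1] - side) // 2
            square = mean_image[r0 : r0 + side, c0 : c0 + side]
            if side != config.raw_image_size:
                square = _bilinear_resize_square(square, config.raw_image_size)
            raw_rows.append(square.ravel())
    features = np.vstack(feat_rows) if need_backend else None
    raw_pixels = np.vstack(raw_rows) if need_raw else None
    return features, raw_pixels


def _single_modality_search(X, y, slot: str, config: PipelineConfig, gamma_grid, seed: int):
    """Grid search with the fusion weight pinned to one endpoint."""
    if slot == "spectral":
        return grid_search(
            X, X, y,
            mu_grid=(1.0,), C_grid=config.C_grid,
            gamma_s_grid=gamma_grid, gamma_w_grid=(1.0,),
            cv_folds=config.svm_folds, seed=seed,
        )
    return grid_search(
        X, X, y,
        mu_grid=(0.0,), C_grid=config.C_grid,
        gamma_s_grid=(1.0,), gamma_w_grid=gamma_grid,
        cv_folds=config.svm_folds, seed=seed,
    )


def _finalize_model(
    name: str,
    best: KernelConfig,
    cv_table: pd.DataFrame,
    Xs_tr, Xw_tr, Xs_te, Xw_te,
    y_tr, y_te,
    train_ids,
) -> ModelResult:
    model = train_fused(Xs_tr, Xw_tr, y_tr, best, sample_ids=train_ids)
    pred_tr = predict(model, Xs_tr, Xw_tr)
    pred_te = predict(model, Xs_te, Xw_te)
    rep_tr = evaluate(pred_tr, y_tr)
    rep_te = evaluate(pred_te, y_te)
    return ModelResult(
        name=name,
        config=best,
        train_accuracy=rep_tr.accuracy,
        test_accuracy=rep_te.accuracy,
        train_report=rep_tr,
        test_report=rep_te,
        test_predictions=pred_te,
        cv_table=cv_table,
    )


def run_pipeline(
    config: PipelineConfig,
    seed: int | None = None,
    include_pretreatment_table: bool = False,
) -> ComparisonResult:
    """Execute the configured experiment and evaluate every requested model."""
    seed = config.seed if seed is None else int(seed)
    unknown = set(config.models) - set(ALL_MODELS)
    if unknown:
        raise ValueError(f"unknown model name(s): {sorted(unknown)}")
    manifest = dataset_manifest(config.scene, config.n_per_class, seed)

    spectra = _stream_spectra(config, manifest)
    split = ks_split(spectra, ratio=config.ratio, stratified=config.stratified)
    tr = spectra.rows_for_ids(split.train_ids)
    te = spectra.rows_for_ids(split.test_ids)
    train_ss, test_ss = spectra.subset_rows(tr), spectra.subset_rows(te)
    y_tr, y_te = train_ss.labels, test_ss.labels

    pcfg = PreprocessConfig(
        method=config.pretreat, sg_window=config.sg_window, sg_polyorder=config.sg_polyorder
    )
    train_p, pinfo = preprocess(train_ss, pcfg)
    test_p, _ = preprocess(test_ss, pcfg, pinfo.get("msc_reference"))

    need_spa = bool({"spectrum_spa", "fused"} & set(config.models))
    need_backend = bool({"image_features", "fused"} & set(config.models))
    need_raw = "image_raw" in config.models

    selection: BandSelection | None = None
    spa_tr = spa_te = None
    if need_spa:
        selection = select_bands(
            train_p,
            n_min=config.spa_n_min,
            n_max=config.spa_n_max,
            cv_folds=config.spa_folds,
            seed=seed,
            starts=config.spa_starts,
        )
        spa_tr = apply_selection(train_p, selection).spectra
        spa_te = apply_selection(test_p, selection).spectra

    features = raw_pixels = None
    if need_backend or need_raw:
        band_idx = (
            np.asarray(selection.selected_indices, dtype=int)
            if selection is not None
            else np.arange(spectra.n_bands)
        )
        features, raw_pixels = _stream_image_features(
            config, manifest, band_idx, need_backend, need_raw
        )

    def rows_of(matrix, idx):
        return None if matrix is None else matrix[idx]

    models: dict = {}
    if "spectrum_raw" in config.models:
        best, table = _single_modality_search(
            train_ss.spectra, y_tr, "spectral", config, config.gamma_s_grid, seed
        )
        models["spectrum_raw"] = _finalize_model(
            "spectrum_raw", best, table,
            train_ss.spectra, train_ss.spectra, test_ss.spectra, test_ss.spectra,
            y_tr, y_te, split.train_ids,
        )
    if "spectrum_spa" in config.models:
        best, table = _single_modality_search(
            spa_tr, y_tr, "spectral", config, config.gamma_s_grid, seed
        )
        models["spectrum_spa"] = _finalize_model(
            "spectrum_spa", best, table, spa_tr, spa_tr, spa_te, spa_te,
            y_tr, y_te, split.train_ids,
        )
    if "image_raw" in config.models:
        xr_tr, xr_te = rows_of(raw_pixels, tr), rows_of(raw_pixels, te)
        best, table = _single_modality_search(
            xr_tr, y_tr, "image", config, config.gamma_w_grid, seed
        )
        models["image_raw"] = _finalize_model(
            "image_raw", best, table, xr_tr, xr_tr, xr_te, xr_te,
            y_tr, y_te, split.train_ids,
        )
    if "image_features" in config.models:
        xf_tr, xf_te = rows_of(features, tr), rows_of(features, te)
        best, table = _single_modality_search(
            xf_tr, y_tr, "image", config, config.gamma_w_grid, seed
        )
        models["image_features"] = _finalize_model(
            "image_features", best, table, xf_tr, xf_tr, xf_te, xf_te,
            y_tr, y_te, split.train_ids,
        )
    if "fused" in config.models:
        xf_tr, xf_te = rows_of(features, tr), rows_of(features, te)
        best, table = grid_search(
            spa_tr, xf_tr, y_tr,
            mu_grid=config.mu_grid, C_grid=config.C_grid,
            gamma_s_grid=config.gamma_s_grid, gamma_w_grid=config.gamma_w_grid,
            cv_folds=config.svm_folds, seed=seed,
        )
        models["fused"] = _finalize_model(
            "fused", best, table, spa_tr, xf_tr, spa_te, xf_te,
            y_tr, y_te, split.train_ids,
        )

    kind = {
        "spectrum_raw": ("spectrum", "raw-SVM"),
        "spectrum_spa": ("spectrum", "SPA-SVM"),
        "image_raw": ("image", "raw-SVM"),
        "image_features": ("image", "conv-features-SVM"),
        "fused": ("spectrum+image", "fused-kernel-SVM"),
    }
    model_table = pd.DataFrame(
        [
            {
                "data": kind[name][0],
                "method": kind[name][1],
                "model": name,
                "train_accuracy": res.train_accuracy,
                "test_accuracy": res.test_accuracy,
            }
            for name, res in models.items()
        ]
    )

    pretreatment_table = None
    if include_pretreatment_table:
        pre_rows = []
        for method in PRETREATMENTS:
            mcfg = PreprocessConfig(
                method=method, sg_window=config.sg_window, sg_polyorder=config.sg_polyorder
            )
            tr_p, info = preprocess(train_ss, mcfg)
            te_p, _ = preprocess(test_ss, mcfg, info.get("msc_reference"))
            best, table = _single_modality_search(
                tr_p.spectra, y_tr, "spectral", config, config.gamma_s_grid, seed
            )
            res = _finalize_model(
                f"pretreat_{method}", best, table,
                tr_p.spectra, tr_p.spectra, te_p.spectra, te_p.spectra,
                y_tr, y_te, split.train_ids,
            )
            pre_rows.append(
                {
                    "pretreatment": method,
                    "train_accuracy": res.train_accuracy,
                    "test_accuracy": res.test_accuracy,
                }
            )
        pretreatment_table = pd.DataFrame(pre_rows)

    return ComparisonResult(
        manifest=manifest,
        spectra=spectra,
        split=split,
        selection=selection,
        models=models,
        model_table=model_table,
        pretreatment_table=pretreatment_table,
    )


def run_comparison(config: PipelineConfig, seed: int | None = None) -> ComparisonResult:
    """The full experiment grid: model table plus pretreatment table."""
    return run_pipeline(config, seed=seed, include_pretreatment_table=True)
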