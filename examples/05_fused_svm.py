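"""Train the fused-kernel SVM and compare it with its endpoints.

Builds spectral (SPA-selected, SNV) and image (seeded-conv) features for
a small dataset, grid-searches the fusion weight mu together with C and
the RBF widths, and prints test accuracies of the fused model against
the mu = 1 (spectral-only) and mu = 0 (image-only) endpoints.
"""

import mycospec as ms
from mycospec.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    scene=ms.default_scene_config(n_bands=100, image_size=64),
    n_per_class=15,
    spa_n_max=8,
    spa_starts=20,
    out_size=64,
    mu_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    C_grid=(1.0, 10.0, 100.0),
    gamma_s_grid=("scale", 0.1),
    gamma_w_grid=("scale", 0.1),
    svm_folds=3,
    models=("spectrum_spa", "image_features", "fused"),
)
result = run_pipeline(config, seed=3)

print(f"train/test split: {len(result.split.train_ids)}/{len(result.split.test_ids)} "
      f"(Kennard-Stone, stratified 4:1)")
print(f"SPA selected {result.selection.n_bands} bands, "
      f"CV RMSE {result.selection.chosen_rmse:.3f}\n")

for name in ("spectrum_spa", "image_features", "fused"):
    res = result.models[name]
    extra = f", mu={res.config.mu:.2f}" if name == "fused" else ""
    print(f"{name:16s} test accuracy {res.test_accuracy:.3f} "
          f"(C={res.config.C:g}{extra})")

fused = result.models["fused"]
print("\nfused-model confusion matrix (rows = true grade):")
print(fused.test_report.confusion)
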