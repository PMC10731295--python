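"""Extract convolutional texture features from band images.

Grayscale images at three wavelengths are center-cropped, resized,
normalized, and pushed through the deterministic seeded-conv backend to
a 2048-d vector per sample (mean-pooled over bands). A linear probe then
checks that the features separate the widest (grade 0) from the
narrowest (grade 3) mycelium.
"""

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

import mycospec as ms
from mycospec.image_features import SeededConvBackend, band_images_from_cube, prepare_image

scene = ms.default_scene_config(n_bands=60, image_size=64)
backend = SeededConvBackend(seed=0)
print(f"backend: {backend.name}, feature_dim={backend.feature_dim}, deterministic")

features, labels = [], []
seeds = np.random.SeedSequence(5).generate_state(32)
for i, label in enumerate([0, 3] * 16):
    sample = ms.generate_sample(scene, label, int(seeds[i] & 0x7FFFFFFF))
    cube = ms.calibrate(sample.raw_cube, sample.references)
    band_images = band_images_from_cube(cube, [10, 30, 50])
    vecs = [backend(prepare_image(img, out_size=64)) for img in band_images]
    features.append(np.mean(vecs, axis=0))
    labels.append(label)

X, y = np.array(features), np.array(labels)
print(f"feature matrix: {X.shape}")

probe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
acc = cross_val_score(probe, X, y, cv=StratifiedKFold(4, shuffle=True, random_state=0)).mean()
print(f"grade 0 vs 3 linear-probe CV accuracy: {acc:.2f} (chance = 0.50)")
print("-> the texture features carry the filament-width signal")
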