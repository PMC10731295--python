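"""SPA chain correctness (vs brute force) and RMSE-based band selection."""

import numpy as np
import pytest

import mycospec as ms
from mycospec.band_selection import CollinearityError, select_bands
from mycospec.calibration import SpectrumSet


def brute_force_spa(X, start, N):
    """Independent oracle: explicit orthogonal-complement projections."""
    X = np.asarray(X, dtype=float)
    selected = [start]
    for _ in range(1, N):
        V = X[:, selected]
        P = np.eye(X.shape[0]) - V @ np.linalg.pinv(V)
        norms = np.array(
            [
                np.linalg.norm(P @ X[:, j]) if j not in selected else -np.inf
                for j in range(X.shape[1])
            ]
        )
        selected.append(int(np.argmax(norms)))  # first max -> lowest index ties
    return selected


def test_orthogonal_columns_selected_in_descending_norm_order():
    """Projections leave mutually orthogonal columns unchanged."""
    Q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(6, 4)))
    X = Q * np.array([4.0, 3.0, 2.0, 1.0])
    assert ms.spa_chain(X, 0, 3) == [0, 1, 2]
    # starting elsewhere still walks down the remaining norms
    assert ms.spa_chain(X, 2, 3) == [2, 0, 1]


def test_chain_of_one_is_the_start():
    X = np.random.default_rng(0).normal(size=(5, 4))
    assert ms.spa_chain(X, 3, 1) == [3]


@pytest.mark.parametrize("seed", range(5))
def test_chain_matches_bruteforce_oracle(seed):
    X = np.random.default_rng(seed).normal(size=(8, 6))
    for start in range(6):
        assert ms.spa_chain(X, start, 4) == brute_force_spa(X, start, 4)


def test_sequential_projections_are_orthogonal():
    """Each stored projected column is orthogonal to its predecessor's."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(10, 7))
    chain = ms.spa_chain(X, 2, 5)
    # reconstruct the projected columns step by step
    work = X.copy()
    for prev, cur in zip(chain, chain[1:]):
        v = work[:, prev]
        unsel = [j for j in range(7) if j not in chain[: chain.index(cur)]]
        work[:, unsel] -= np.outer(v, (v @ work[:, unsel]) / (v @ v))
        inner = abs(work[:, cur] @ v) / (np.linalg.norm(work[:, cur]) * np.linalg.norm(v))
        assert inner < 1e-8


def test_chain_is_deterministic():
    X = np.random.default_rng(5).normal(size=(9, 8))
    assert ms.spa_chain(X, 1, 5) == ms.spa_chain(X, 1, 5)


def test_invalid_inputs_rejected():
    X = np.random.default_rng(0).normal(size=(5, 4))
    with pytest.raises(ValueError):
        ms.spa_chain(X, 0, 5)  # N > min(n-1, B)
    with pytest.raises(ValueError):
        ms.spa_chain(X, 9, 2)  # start out of range
    Xz = X.copy()
    Xz[:, 2] = 0.0
    with pytest.raises(ValueError, match="zero"):
        ms.spa_chain(Xz, 0, 2)


def test_collinear_exhaustion_reports_achievable_n():
    rng = np.random.default_rng(1)
    u = rng.normal(size=6)
    X = np.outer(u, rng.uniform(0.5, 2.0, 5))  # rank one
    with pytest.raises(CollinearityError, match="achievable N = 1"):
        ms.spa_chain(X, 0, 3)


def _planted_spectrumset(seed, n=60, n_bands=40, planted=(5, 18, 33)):
    """Grade labels an exact linear function of three planted bands."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_bands)
    X = np.zeros((n, n_bands))
    for i in range(n):
        for c, wd, a in zip(
            rng.uniform(0, 1, 4), rng.uniform(0.05, 0.2, 4), rng.normal(0, 0.3, 4)
        ):
            X[i] += a * np.exp(-0.5 * ((t - c) / wd) ** 2)
    y = np.repeat([0, 1, 2, 3], n // 4)
    rng.shuffle(y)
    b1, b2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    X[:, planted[0]] = b1
    X[:, planted[1]] = b2
    X[:, planted[2]] = (y - b1 + b2) / 2.0  # y = b1 - b2 + 2*b3
    X += rng.normal(0, 0.01, X.shape)
    return SpectrumSet(
        X,
        np.linspace(400, 1000, n_bands),
        y,
        np.array([f"s{i}" for i in range(n)], dtype=object),
    )


def test_planted_signal_recovered():
    ss = _planted_spectrumset(0)
    sel = select_bands(ss, n_min=1, n_max=6, cv_folds=5, seed=0)
    assert sel.n_bands >= 3
    assert {5, 18, 33} <= set(sel.selected_indices)
    # RMSE curve drops sharply once all informative bands are in
    assert sel.rmse_curve[3] < 0.5 * sel.rmse_curve[1]


def test_fixed_chain_length():
    ss = _planted_spectrumset(1)
    sel = select_bands(ss, n_min=5, n_max=5, cv_folds=5, seed=0)
    assert sel.n_bands == 5
    assert len(sel.selected_indices) == 5


def test_rmse_curve_reproducible_for_fixed_seed():
    ss = _planted_spectrumset(2)
    a = select_bands(ss, n_min=1, n_max=4, cv_folds=4, seed=9)
    b = select_bands(ss, n_min=1, n_max=4, cv_folds=4, seed=9)
    assert a.rmse_curve == b.rmse_curve
    assert a.selected_indices == b.selected_indices


class TestApplySelection:
    def _selection(self, indices, wl):
        return ms.BandSelection(
            selected_indices=list(indices),
            selected_wavelengths_nm=[wl[i] for i in indices],
            start_index=indices[0],
            n_bands=len(indices),
            rmse_curve={len(indices): 0.0},
            chosen_rmse=0.0,
        )

    def test_identity_selection(self, mini_spectra):
        sel = self._selection(list(range(mini_spectra.n_bands)), mini_spectra.wavelengths_nm)
        out = ms.apply_selection(mini_spectra, sel)
        assert np.array_equal(out.spectra, mini_spectra.spectra)

    def test_columns_follow_chain_order(self, mini_spectra):
        sel = self._selection([2, 0], mini_spectra.wavelengths_nm)
        out = ms.apply_selection(mini_spectra, sel)
        assert np.array_equal(out.spectra[:, 0], mini_spectra.spectra[:, 2])
        assert np.array_equal(out.spectra[:, 1], mini_spectra.spectra[:, 0])

    def test_wavelength_round_trip(self, mini_spectra):
        sel = self._selection([7, 3, 11], mini_spectra.wavelengths_nm)
        out = ms.apply_selection(mini_spectra, sel)
        assert np.allclose(out.wavelengths_nm, sel.selected_wavelengths_nm)

    def test_out_of_range_rejected(self, mini_spectra):
        sel = self._selection([0, mini_spectra.n_bands], np.arange(mini_spectra.n_bands + 1.0))
        with pytest.raises(IndexError):
            ms.apply_selection(mini_spectra, sel)
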