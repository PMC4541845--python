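"""SPA wavelength selection and the PLS-DA machinery behind it."""

import numpy as np
import pytest

from kernelspec import (one_hot, plsda_choose_components, plsda_coef_select,
                        plsda_fit, plsda_predict, spa_choose_n, spa_select)
from kernelspec.band_selection import _rmsecv_plsda


def spa_oracle(X, start, n_select):
    """Brute-force successive orthogonalization, recomputed from scratch each
    round: candidate j's score is the norm of its residual after projecting
    out the span of ALL selected original columns (via QR)."""
    X = np.asarray(X, float)
    selected = [start]
    for _ in range(1, n_select):
        Q, _ = np.linalg.qr(X[:, selected])
        best, best_norm = None, -1.0
        for j in range(X.shape[1]):
            if j in selected:
                continue
            r = X[:, j] - Q @ (Q.T @ X[:, j])
            nrm = np.linalg.norm(r)
            if nrm > best_norm + 1e-12:
                best, best_norm = j, nrm
        if best_norm <= 1e-10 * np.linalg.norm(X, axis=0).max():
            break
        selected.append(best)
    return selected


class TestSpaSelect:
    def test_orthogonal_columns_selected_by_descending_norm(self):
        X = np.diag([3.0, 7.0, 5.0])
        X = np.vstack([X, np.zeros(3)])
        # start at 0; projections leave orthogonal columns untouched
        assert spa_select(X, start=0, n_select=3) == [0, 1, 2]

    def test_collinear_column_never_selected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        X[:, 2] = 2.0 * X[:, 0]
        sel = spa_select(X, start=0, n_select=3)
        assert 2 not in sel

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n, m = rng.integers(5, 9), rng.integers(8, 13)
            X = rng.normal(size=(n, m))
            start = int(rng.integers(0, m))
            assert spa_select(X, start, int(n)) == spa_oracle(X, start, int(n))

    def test_selected_columns_linearly_independent(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 12))
        sel = spa_select(X, 0, 8)
        assert np.linalg.matrix_rank(X[:, sel]) == len(sel)

    def test_rank_exhaustion_stops_early_with_warning(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 2))
        X = base @ rng.normal(size=(2, 6))        # rank 2, 6 columns
        with pytest.warns(UserWarning, match="stopped early"):
            sel = spa_select(X, 0, 5)
        assert len(sel) <= 2

    def test_zero_column_rejected(self):
        X = np.ones((4, 3))
        X[:, 1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            spa_select(X, 0, 2)


def _sparse_signal_data(seed, n=120, bands=30, informative=(4, 13, 22)):
    """Class structure carried by exactly three bands; the rest pure noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), n // 4)
    means = rng.normal(scale=3.0, size=(4, len(informative)))
    X = rng.normal(size=(n, bands))
    for c in range(4):
        X[np.ix_(labels == c, informative)] += means[c]
    return X, labels, informative


class TestSpaChooseN:
    def test_sparse_signal_plateaus_at_three_bands(self):
        X, labels, informative = _sparse_signal_data(seed=5)
        res = spa_choose_n(X, labels, n_grid=range(1, 9), seed=0)
        best = min(res.rmse_trace.values())
        assert res.rmse_trace[3] <= 1.01 * best      # plateau reached by N=3
        assert len(res.selected) <= 5
        assert set(informative) <= set(res.selected[:5])

    def test_single_size_grid_returns_that_size(self):
        X, labels, _ = _sparse_signal_data(seed=6)
        res = spa_choose_n(X, labels, n_grid=[1], seed=0)
        assert len(res.selected) == 1
        assert list(res.rmse_trace) == [1]

    def test_pure_noise_still_returns_valid_result(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 12))
        labels = np.repeat(np.arange(4), 25)
        res = spa_choose_n(X, labels, n_grid=[2, 4, 6], seed=0)
        assert set(res.selected) <= set(range(12))
        assert len(set(res.selected)) == len(res.selected)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError, match="two classes"):
            spa_choose_n(X, np.zeros(10), n_grid=[2])


class TestPlsda:
    def test_rank_one_relation_fit_exactly(self):
        """With zero-mean orthogonal predictors, a single latent variable
        captures a response that is an exact multiple of one column."""
        n = 30
        i = np.arange(n)
        X = np.stack([np.cos(np.pi * k * (i + 0.5) / n) for k in range(1, 6)], axis=1)
        y = X[:, 2] * 1.7
        model = plsda_fit(X, y[:, None], n_components=1)
        pred = plsda_predict(model, X)
        assert np.linalg.norm(pred[:, 0] - y) / np.linalg.norm(y) < 1e-6

    def test_column_response_fit_exactly_at_full_rank(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 5))
        y = X[:, 2] * 1.7
        model = plsda_fit(X, y[:, None], n_components=5)
        pred = plsda_predict(model, X)
        assert np.linalg.norm(pred[:, 0] - y) / np.linalg.norm(y) < 1e-6

    def test_orthonormal_design_recovers_coefficients(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 6)))
        C = rng.normal(size=(6, 3))
        Y = Q @ C
        model = plsda_fit(Q, Y, n_components=6)
        np.testing.assert_allclose(model.coefficients, C, atol=1e-6)

    def test_full_rank_fit_matches_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 6))
        Y = rng.normal(size=(25, 3))
        model = plsda_fit(X, Y, n_components=6)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        np.testing.assert_allclose(plsda_predict(model, X) - Y.mean(0),
                                   Xc @ beta, atol=1e-6)

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 10))
        labels = rng.permutation(np.repeat(np.arange(4), 30))
        Y, _ = one_hot(labels)
        rmse = _rmsecv_plsda(X, Y, labels, n_components=4, seed=0)
        # chance RMSE for one-hot 4 classes ~ sqrt(p(1-p)) pooled = ~0.43
        assert 0.38 < rmse < 0.52

    def test_component_cap_warns(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 2))
        with pytest.warns(UserWarning, match="capped"):
            model = plsda_fit(X, Y, n_components=10)
        assert model.n_components == 3


class TestChooseComponents:
    def test_rank_two_signal_plus_noise(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(80, 2))
        X = scores @ rng.normal(size=(2, 12)) + 0.05 * rng.normal(size=(80, 12))
        Y = scores @ rng.normal(size=(2, 3))
        assert plsda_choose_components(X, Y, max_components=8) in (2, 3)

    def test_noiseless_rank_one_needs_one(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(50, 1))
        X = t @ rng.normal(size=(1, 6))
        Y = t @ rng.normal(size=(1, 2))
        assert plsda_choose_components(X, Y, max_components=5) == 1

    def test_max_one_returns_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 2))
        assert plsda_choose_components(X, Y, max_components=1) == 1


class TestCoefSelect:
    def test_single_active_band(self):
        coef = np.zeros((10, 4))
        coef[7, 2] = 0.9
        model = plsda_fit(np.eye(10), np.eye(10)[:, :4], 2)
        model.coefficients = coef
        assert plsda_coef_select(model, 1) == [7]

    def test_all_bands_is_a_permutation(self):
        rng = np.random.default_rng(8)
        model = plsda_fit(rng.normal(size=(20, 6)), rng.normal(size=(20, 3)), 3)
        sel = plsda_coef_select(model, 6)
        assert sorted(sel) == list(range(6))

    def test_order_matches_independent_sort(self):
        rng = np.random.default_rng(9)
        coef = rng.normal(size=(15, 4))
        model = plsda_fit(np.eye(15), np.eye(15)[:, :4], 2)
        model.coefficients = coef
        scores = np.abs(coef).max(axis=1)
        expected = sorted(range(15), key=lambda i: (-scores[i], i))
        assert plsda_coef_select(model, 15) == expected
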