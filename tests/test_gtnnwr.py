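"""GTNNWR: splits, distances, OLS head, metrics, forward contracts, training."""

import numpy as np
import pytest

from spatioepi.gtnnwr import (
    GTNNWRConfig,
    GTNNWRModel,
    compute_distances,
    compute_metrics,
    fit_global_ols,
    split_data,
)
from spatioepi.gtnnwr.nets import MLP
from spatioepi.synthetic import simulate_nonstationary_panel


@pytest.fixture(scope="module")
def small_panel():
    return simulate_nonstationary_panel(nrows=3, ncols=4, years=6, noise_sd=0.3, seed=21)


@pytest.fixture(scope="module")
def tiny_trained(small_panel):
    panel, _ = small_panel
    cfg = GTNNWRConfig(swnn_hidden=(16,), epochs=30, log_interval=10)
    return GTNNWRModel(cfg).fit(panel)


class TestSplit:
    def test_published_sizes(self):
        tr, va, te = split_data(1440, (0.75, 0.10, 0.15), seed=48)
        assert (len(tr), len(va), len(te)) == (1080, 144, 216)

    def test_disjoint_exhaustive_reproducible(self):
        a = split_data(517, seed=48)
        b = split_data(517, seed=48)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        allidx = np.concatenate(a)
        assert len(np.unique(allidx)) == 517

    def test_all_training_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            tr, va, te = split_data(100, (1.0, 0.0, 0.0))
        assert len(tr) == 100 and len(va) == 0 and len(te) == 0

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="20"):
            split_data(19)

    def test_bad_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_data(100, (0.5, 0.2, 0.2))


class TestDistances:
    def test_three_four_five(self):
        d = compute_distances([(0, 0), (3, 4)], [0, 0], [(0, 0), (3, 4)], [0, 0])
        assert d.d_s[0, 1] == pytest.approx(5.0)
        assert d.d_s[0, 0] == 0.0 and d.d_t[0, 1] == 0.0
        assert np.allclose(d.d_s, d.d_s.T)

    def test_temporal_absolute_difference(self):
        d = compute_distances([(0, 0)], [1991.0], [(0, 0), (0, 0)], [1995.0, 1980.0])
        assert d.d_t.tolist() == [[4.0, 11.0]]

    def test_train_scaler_applied_without_leakage(self, tiny_trained):
        m = tiny_trained
        d_test = m._scaled_distances(m.idx_test)
        d_train = m._scaled_distances(m.idx_train)
        assert d_train.d_s.max() <= 1.0 + 1e-12
        assert d_train.d_s.min() >= -1e-12
        # test distances may exceed the train bounds: bounds were not re-fit
        assert d_test.d_s.max() >= d_train.d_s.max() - 1e-12


class TestOLS:
    def test_exact_line(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones(30), x])
        beta = fit_global_ols(X, 2 * x + 1)
        assert beta == pytest.approx([1.0, 2.0], abs=1e-12)

    def test_matches_normal_equations(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        beta = fit_global_ols(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(beta, oracle, atol=1e-8)

    def test_collinear_named(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_global_ols(X, x)


class TestMetrics:
    def test_perfect_fit(self, rng):
        y = rng.normal(size=25)
        m = compute_metrics(y, y, normalizer=4.0)
        assert m.r2 == 1.0 and m.rmse == 0.0 and m.mae == 0.0 and m.mbe == 0.0

    def test_constant_shift(self, rng):
        y = rng.normal(size=25)
        m = compute_metrics(y, y + 2.0, normalizer=4.0)
        assert m.mbe == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.nrmse == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        y = rng.normal(size=40)
        yhat = y + rng.normal(0, 0.5, size=40)
        norm = 3.0
        m = compute_metrics(y, yhat, norm)
        sse = sum((a - b) ** 2 for a, b in zip(yhat, y))
        ybar = sum(y) / len(y)
        assert m.r2 == pytest.approx(1 - sse / sum((v - ybar) ** 2 for v in y), abs=1e-10)
        assert m.rmse == pytest.approx((sse / len(y)) ** 0.5, abs=1e-10)
        assert m.mae == pytest.approx(sum(abs(a - b) for a, b in zip(yhat, y)) / 40, abs=1e-10)
        assert m.mbe == pytest.approx(sum(a - b for a, b in zip(yhat, y)) / 40, abs=1e-10)
        assert m.nmse_loss == pytest.approx(sse / (40 * norm**2), abs=1e-12)
        assert m.rmse >= abs(m.mbe)

    def test_empty_split_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.array([]), np.array([]), 1.0)


class TestForward:
    def test_unit_weights_reduce_to_ols(self, tiny_trained):
        m = tiny_trained
        idx = m.idx_test
        yhat, w, _ = m.forward(idx, force_unit_weights=True)
        assert np.allclose(yhat, m.X[idx] @ m.beta_ols, atol=1e-10)
        assert np.all(w == 1.0)

    def test_dropout_mode_contract(self, tiny_trained):
        m = tiny_trained
        idx = m.idx_val
        a, _, _ = m.forward(idx, training=True)
        b, _, _ = m.forward(idx, training=True)
        assert not np.allclose(a, b)  # dropout active
        c, _, _ = m.forward(idx, training=False)
        d, _, _ = m.forward(idx, training=False)
        assert np.array_equal(c, d)

    def test_weight_vector_per_coefficient(self, tiny_trained):
        m = tiny_trained
        _, w, dist = m.forward(m.idx_val[:5])
        assert w.shape == (5, m.X.shape[1])
        assert dist.d_s.shape == (5, len(m.idx_train))


class TestTraining:
    def test_zero_epochs_returns_initialization(self, small_panel):
        panel, _ = small_panel
        cfg = GTNNWRConfig(swnn_hidden=(8,), epochs=0)
        m = GTNNWRModel(cfg).fit(panel)
        # w = 1 init means the untrained model equals global OLS
        yhat, w, _ = m.forward(m.idx_test)
        assert np.allclose(yhat, m.X[m.idx_test] @ m.beta_ols, atol=1e-4)

    def test_bit_identical_history_under_seed(self, small_panel):
        panel, _ = small_panel
        cfg = GTNNWRConfig(swnn_hidden=(8,), epochs=12, log_interval=4)
        h1 = GTNNWRModel(cfg).fit(panel).history
        h2 = GTNNWRModel(cfg).fit(panel).history
        assert h1 == h2

    def test_stationary_data_keeps_weights_near_one(self):
        beta = {"b0": lambda x, y, t: 1.5 + 0 * x, "b1": lambda x, y, t: 2.0 + 0 * x}
        panel, _ = simulate_nonstationary_panel(
            nrows=3, ncols=4, years=6, beta_spec=beta, noise_sd=0.0, seed=13
        )
        cfg = GTNNWRConfig(swnn_hidden=(16,), epochs=150, log_interval=50)
        m = GTNNWRModel(cfg).fit(panel)
        _, w, _ = m.forward(np.arange(panel.n_records))
        assert np.mean(np.abs(w - 1.0)) < 0.05
        assert m.evaluate("test").rmse <= m.evaluate("test", ols_baseline=True).rmse * 1.05

    def test_divergence_aborts_with_diagnostic(self, small_panel):
        panel, _ = small_panel
        cfg = GTNNWRConfig(swnn_hidden=(8,), epochs=5, normalizer=1e-300)
        with pytest.raises(FloatingPointError, match="diverged"):
            GTNNWRModel(cfg).fit(panel)

    def test_missing_coordinates_rejected(self, small_panel):
        panel, _ = small_panel
        import pandas as pd

        bare = panel.df.drop(columns=["x", "y"])
        from spatioepi.panel import PanelDataset

        p2 = PanelDataset(bare, panel.covariate_names)
        with pytest.raises(ValueError, match="coordinates"):
            GTNNWRModel(GTNNWRConfig(epochs=1)).fit(p2)


class TestCoefficients:
    def test_surface_shape_and_names(self, tiny_trained, small_panel):
        panel, _ = small_panel
        surf = tiny_trained.extract_coefficients()
        assert surf.beta.shape == (panel.n_records, 3)
        assert surf.names == ["intercept", "b1", "b2"]
        imp = surf.yearly_importance()
        assert len(imp) == 6

    def test_null_factor_ranks_last(self):
        """A covariate absent from the generator gets the smallest mean |beta|."""
        beta = {
            "b0": lambda x, y, t: 1.0 + 0 * x,
            "live": lambda x, y, t: 2.0 + 0.3 * x,
            "dead": lambda x, y, t: 0.0 * x,
        }
        panel, _ = simulate_nonstationary_panel(
            nrows=4, ncols=4, years=8, beta_spec=beta, noise_sd=0.2, seed=17
        )
        cfg = GTNNWRConfig(swnn_hidden=(16,), epochs=200, log_interval=100)
        m = GTNNWRModel(cfg).fit(panel)
        surf = m.extract_coefficients()
        means = surf.as_frame()[["live", "dead"]].abs().mean()
        assert means["dead"] < means["live"]
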