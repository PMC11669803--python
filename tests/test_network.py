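"""Node-wise LASSO estimation of the cross-lagged weight matrix."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from clpnet import (
    CrossLaggedPanelNetwork,
    FitConfig,
    SimulationConfig,
    display_threshold,
    fit_clpn,
    fit_node_regression,
    generate_cohort,
    standardize_nodes,
)
from clpnet import nodes as nd

from conftest import latent_frames


class TestStandardize:
    def test_columns_become_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(3, 2, (200, 5)), columns=list("abcde"))
        z = standardize_nodes(df)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.allclose(z.std(axis=0, ddof=0), 1.0)

    def test_idempotent(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [0.0, 5, 1]})
        once = standardize_nodes(df)
        twice = standardize_nodes(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "PAs": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="PAs"):
            standardize_nodes(df)


class TestNodeRegression:
    def test_lambda_zero_equals_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((500, 24))
        beta = rng.normal(0, 0.2, 24)
        y = x @ beta + rng.standard_normal(500) * 0.5
        cfg = FitConfig(lambda_selection="fixed", fixed_lambda=0.0)
        nf = fit_node_regression(y, x, None, cfg)
        xc = np.hstack([np.ones((500, 1)), x])
        oracle = np.linalg.solve(xc.T @ xc, xc.T @ y)[1:]
        assert np.abs(nf.coef - oracle).max() < 1e-6

    def test_lambda_zero_with_covariates_matches_joint_ols(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((400, 10))
        z = pd.DataFrame({"age": rng.integers(17, 23, 400),
                          "sex": rng.integers(0, 2, 400)})
        y = x[:, 0] * 0.5 + 0.3 * z["sex"].to_numpy() + rng.standard_normal(400)
        cfg = FitConfig(lambda_selection="fixed", fixed_lambda=0.0)
        nf = fit_node_regression(y, x, z, cfg)
        design = np.hstack([np.ones((400, 1)), z.to_numpy(dtype=float), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)[3:]
        assert np.abs(nf.coef - oracle).max() < 1e-6

    def test_full_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((300, 24))
        y = rng.standard_normal(300)
        cfg = FitConfig(lambda_selection="fixed", fixed_lambda=10.0)
        nf = fit_node_regression(y, x, None, cfg)
        assert (nf.coef == 0).all()

    def test_recovers_single_strong_predictor(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2000, 24))
        y = 0.8 * x[:, 0] + rng.standard_normal(2000) * 0.1
        nf = fit_node_regression(y, x, None, FitConfig(seed=4))
        assert 0.7 <= nf.coef[0] <= 0.9
        assert np.abs(nf.coef[1:]).max() < 0.02

    def test_degenerate_predictor_rejected(self):
        x = np.ones((100, 3))
        with pytest.raises(ValueError, match="degenerate|zero-variance"):
            fit_node_regression(np.random.default_rng(0).standard_normal(100),
                                x, None, FitConfig())

    def test_cv_needs_enough_samples(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="cv_folds"):
            fit_node_regression(rng.standard_normal(15),
                                rng.standard_normal((15, 3)), None,
                                FitConfig(cv_folds=10))


class TestFitClpn:
    def test_shrinkage_monotone_in_lambda(self):
        cfg = SimulationConfig(n_participants=800, seed=13)
        _, truth = generate_cohort(cfg)
        w1, w2 = latent_frames(truth)
        counts = []
        for lam in (0.0, 0.01, 0.05, 0.1, 0.3):
            net = fit_clpn(w1, w2, None,
                           FitConfig(lambda_selection="fixed", fixed_lambda=lam))
            counts.append(int((net.cross_lagged != 0).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_autoregressive_diagonal_recovery(self):
        t = np.diag([0.5] * 24)
        cfg = SimulationConfig(n_participants=5000, seed=29, truth_matrix=t,
                               noise_sd=1.0)
        _, truth = generate_cohort(cfg)
        w1, w2 = latent_frames(truth)
        net = fit_clpn(w1, w2, None, FitConfig(seed=29))
        # standardization rescales: compare on the standardized truth scale
        diag = net.autoregressive
        assert (diag > 0.3).all() and (diag < 0.65).all()

    def test_null_truth_is_sparsistent_under_1se_rule(self):
        zeros = []
        for s in range(5):
            cfg = SimulationConfig(
                n_participants=2000, seed=500 + s,
                truth_matrix=np.diag([0.3] * 24), noise_sd=1.0,
            )
            _, truth = generate_cohort(cfg)
            w1, w2 = latent_frames(truth)
            net = fit_clpn(w1, w2, None,
                           FitConfig(lambda_selection="cv_1se", seed=s))
            off = ~np.eye(24, dtype=bool)
            zeros.append((net.weights[off] == 0).mean())
        assert np.median(zeros) >= 0.95

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_participants=600, seed=37)
        _, truth = generate_cohort(cfg)
        w1, w2 = latent_frames(truth)
        f = FitConfig(cv_folds=5, n_alphas=20, seed=11)
        a = fit_clpn(w1, w2, None, f)
        b = fit_clpn(w1, w2, None, f)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.lambdas, b.lambdas)

    def test_covariates_excluded_from_weight_matrix(self, small_cohort):
        data, truth = small_cohort
        w1, w2 = latent_frames(truth)
        covs = data.wave(1)[nd.COVARIATES].reset_index(drop=True)
        net = fit_clpn(w1, w2, covs,
                       FitConfig(lambda_selection="fixed", fixed_lambda=0.05))
        assert net.weights.shape == (24, 24)
        assert net.covariate_coefs is not None
        assert set(net.covariate_coefs.index) == set(nd.COVARIATES)

    def test_pure_noise_covariate_barely_moves_weights(self):
        cfg = SimulationConfig(n_participants=5000, seed=9)
        _, truth = generate_cohort(cfg)
        w1, w2 = latent_frames(truth)
        f = FitConfig(lambda_selection="fixed", fixed_lambda=0.02)
        base = fit_clpn(w1, w2, None, f).weights
        junk = pd.DataFrame(
            {"junk": np.random.default_rng(1).standard_normal(len(w1))}
        )
        adj = fit_clpn(w1, w2, junk, f).weights
        assert np.abs(base - adj).max() < 0.02

    def test_participant_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        w1 = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"),
                          index=range(50))
        w2 = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"),
                          index=range(1, 51))
        with pytest.raises(ValueError, match="indices differ"):
            fit_clpn(w1, w2, None, FitConfig(lambda_selection="fixed",
                                             fixed_lambda=0.1))

    def test_missing_values_rejected(self):
        w1 = pd.DataFrame(np.random.default_rng(0).standard_normal((50, 3)))
        w2 = w1.copy()
        w2.iloc[0, 0] = np.nan
        with pytest.raises((ValueError, RuntimeError), match="missing"):
            fit_clpn(w1, w2, None, FitConfig(lambda_selection="fixed",
                                             fixed_lambda=0.1))


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = CrossLaggedPanelNetwork(fixed_lambda=0.1,
                                      lambda_selection="fixed")
        params = est.get_params()
        est2 = clone(est).set_params(**params)
        assert est2.get_params() == params

    def test_fit_predict_shapes(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((200, 6))
        y = x @ np.diag([0.4] * 6) + rng.standard_normal((200, 6))
        est = CrossLaggedPanelNetwork(lambda_selection="fixed",
                                      fixed_lambda=0.05).fit(x, y)
        assert est.W_.shape == (6, 6)
        assert est.predict(x).shape == (200, 6)
        assert est.network_.weights is est.W_


class TestDisplayThreshold:
    def _net(self, entries):
        w = np.zeros((24, 24))
        for (i, j), v in entries.items():
            w[i, j] = v
        from clpnet import CLPNetwork

        return CLPNetwork(w, list(nd.NODE_LABELS), list(nd.CONSTRUCT_LABELS),
                          np.zeros(24), 0)

    def test_threshold_filters_weak_edges(self):
        net = self._net({(0, 5): 0.04, (1, 6): 0.06})
        edges = display_threshold(net, 0.05)
        assert len(edges) == 1
        assert edges.iloc[0]["weight"] == pytest.approx(0.06)

    def test_zero_threshold_returns_all_nonzero(self):
        net = self._net({(0, 5): 0.04, (1, 6): -0.06})
        assert len(display_threshold(net, 0.0)) == 2

    def test_zero_matrix_empty(self):
        assert display_threshold(self._net({}), 0.0).empty

    def test_network_never_modified(self):
        net = self._net({(0, 5): 0.04})
        before = net.weights.copy()
        display_threshold(net, 0.05)
        assert np.array_equal(net.weights, before)
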