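"""Encoding GLM: solver optimality, R^2 definition, significance, VIF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls as scipy_nnls

from catglm.glm import (GlmEngine, _r_squared, classify_modulation_change,
                        fit_nnls_l1, max_vif, significance_by_shuffle,
                        subgroup_delta_r2)


def enumerate_nnls_l1(X, y, lam):
    """Oracle: best nonnegative solution over all active sets (exhaustive)."""
    n = X.shape[1]
    best_w, best_obj = np.zeros(n), np.sum(y**2)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            sub = list(subset)
            G = X[:, sub].T @ X[:, sub]
            b = X[:, sub].T @ y - lam / 2.0
            try:
                w_sub = np.linalg.solve(G, b)
            except np.linalg.LinAlgError:
                continue
            if np.any(w_sub < -1e-12):
                continue
            w = np.zeros(n)
            w[sub] = np.clip(w_sub, 0, None)
            obj = np.sum((y - X @ w) ** 2) + lam * w.sum()
            if obj < best_obj - 1e-12:
                best_obj, best_w = obj, w
    return best_w


class TestSolver:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_active_set_enumeration(self, seed):
        """Small designs: solution equals the brute-force optimum to 1e-6."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 6))
        w_true = np.clip(rng.normal(size=6), 0, None)
        y = X @ w_true + 0.1 * rng.normal(size=120)
        for l1_scale in (0.0, 0.02):
            w = fit_nnls_l1(X, np.abs(y), l1_scale=l1_scale, l1_size="response_sum")
            lam = l1_scale * np.abs(y).sum()
            w_ref = enumerate_nnls_l1(X, np.abs(y), lam)
            np.testing.assert_allclose(w, w_ref, atol=1e-6)

    def test_lambda_zero_orthonormal_design_exact_recovery(self):
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(50, 5)))
        w_true = np.array([0.5, 0.0, 2.0, 0.1, 0.0])
        y = Q @ w_true
        w = fit_nnls_l1(Q, y, l1_scale=0.0)
        np.testing.assert_allclose(w, w_true, atol=1e-9)

    def test_lambda_zero_matches_scipy_nnls(self):
        rng = np.random.default_rng(8)
        X = np.abs(rng.normal(size=(80, 10)))
        y = np.abs(rng.normal(size=80))
        w_ref, _ = scipy_nnls(X, y)
        np.testing.assert_allclose(fit_nnls_l1(X, y, l1_scale=0.0), w_ref,
                                   atol=1e-8)

    def test_huge_penalty_zeroes_all_weights(self):
        rng = np.random.default_rng(9)
        X = np.abs(rng.normal(size=(60, 4)))
        y = np.abs(rng.normal(size=60))
        assert np.all(fit_nnls_l1(X, y, l1_scale=1e6) == 0)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_nnls_l1(np.array([[1.0], [np.nan]]), np.ones(2))


class TestRSquared:
    def test_predicting_test_mean_gives_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        assert _r_squared(y, np.full(100, y.mean())) == pytest.approx(0.0)

    def test_perfect_prediction_gives_one(self):
        y = np.arange(10.0)
        assert _r_squared(y, y) == 1.0


class TestCrossValidatedFit:
    def test_weights_always_nonnegative(self, engine):
        fit = engine.cross_validated_fit(0, n_repeats=5, seed=1)
        assert np.all(fit.weights >= 0)

    def test_noiseless_planted_neuron_high_test_r2(self, noiseless_session):
        eng = GlmEngine(noiseless_session)
        fit = eng.cross_validated_fit(0, n_repeats=5, seed=2)
        assert fit.mean_test_r2 > 0.99

    def test_pure_noise_neuron_r2_near_zero(self, trials):
        from catglm.simulate import PlantedKernels, simulate_neural_session
        kernels = PlantedKernels([{("offset", ""): np.array([0.0])}])
        ses = simulate_neural_session(trials, kernels, 15.0, noise_sd=0.5,
                                      trial_gain_cv=0.0, seed=5)
        fit = GlmEngine(ses).cross_validated_fit(0, n_repeats=20, seed=3)
        assert abs(fit.mean_test_r2) < 0.02

    def test_kernel_recovery_on_planted_neuron(self, engine, session):
        fit = engine.cross_validated_fit(0, n_repeats=10, seed=4)
        W = session.meta["ground_truth"]["weights"][0]
        mask = (fit.columns["subgroup"] != "offset").to_numpy()
        corr = np.corrcoef(W[mask], fit.mean_weights[mask])[0, 1]
        assert corr > 0.8

    def test_too_few_trials_error(self, reduced_space, agent, planted_kernels):
        from catglm.simulate import simulate_behavior_session, simulate_neural_session
        tr = simulate_behavior_session(reduced_space, agent, 5, seed=1)
        ses = simulate_neural_session(tr, planted_kernels, 15.0, seed=1)
        with pytest.raises(ValueError):
            GlmEngine(ses).cross_validated_fit(0, n_repeats=2, seed=0)


class TestSignificance:
    def test_planted_neuron_significant_noise_neuron_not(self, engine, trials):
        fit = engine.cross_validated_fit(0, n_repeats=50, seed=1)
        shuf = engine.cross_validated_fit(0, n_repeats=50, seed=2,
                                          shuffle_trials=True)
        assert significance_by_shuffle(fit, shuf)
        assert fit.mean_test_r2 > shuf.mean_test_r2

    def test_identical_distributions_not_significant(self, engine):
        fit = engine.cross_validated_fit(0, n_repeats=30, seed=3)
        assert not significance_by_shuffle(fit, fit)


class TestSubgroupDeltaR2:
    def test_planted_category_neuron_ranks_subgroups(self, engine):
        """delta R^2 is large for the planted subgroup, small for an
        unplanted one (positive/negative control)."""
        fit = engine.cross_validated_fit(0, n_repeats=10, seed=5)
        d_cat = subgroup_delta_r2(engine, 0, fit, "category", seed=6)
        d_mov = subgroup_delta_r2(engine, 0, fit, "movement", seed=7)
        assert d_cat > 0.05
        assert d_cat > d_mov

    def test_unknown_subgroup_errors(self, engine):
        fit = engine.cross_validated_fit(0, n_repeats=5, seed=8)
        with pytest.raises(ValueError):
            subgroup_delta_r2(engine, 0, fit, "no-such-subgroup")


class TestModulationClassification:
    def test_class_assignment_and_ratio(self):
        out = classify_modulation_change([True, True, False, False],
                                         [True, False, True, False])
        assert list(out["class"]) == ["stable", "lost", "gained", "never"]
        assert out.attrs["changed_stable_ratio"] == pytest.approx(2.0)

    def test_all_stable_ratio_zero(self):
        out = classify_modulation_change([True] * 3, [True] * 3)
        assert out.attrs["changed_stable_ratio"] == 0.0

    def test_no_significant_neurons_error(self):
        with pytest.raises(ValueError):
            classify_modulation_change([False, False], [False, False])

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            classify_modulation_change([True], [True, False])


class TestVif:
    def test_orthogonal_design_gives_unit_vifs(self):
        from catglm.design import DesignMatrix
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(300, 6))
        # center before orthogonalizing so the columns stay orthogonal
        # after the VIF's internal centering
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0, keepdims=True))
        cols = pd.DataFrame({
            "set_label": ["a", "a", "b", "b", "c", "c"],
            "level": [""] * 6,
            "offset_s": [0.0, 0.5] * 3,
            "subgroup": ["orientation", "orientation", "category", "category",
                         "choice", "choice"],
            "epoch": ["stimulus", "stimulus", "stimulus", "stimulus",
                      "response", "response"],
        })
        d = DesignMatrix(X=Q, columns=cols, frame_rate_hz=15.0,
                         trial_starts=np.array([0]), frames_per_trial=300,
                         trial_index=pd.DataFrame({"trial_id": [0]}))
        mv, per = max_vif(d, mode="across_epochs")
        assert mv == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_across_epochs_is_infinite(self):
        from catglm.design import DesignMatrix
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        X[:, 3] = X[:, 0]  # stimulus column duplicated in response epoch
        cols = pd.DataFrame({
            "set_label": ["a", "a", "b", "c"],
            "level": [""] * 4,
            "offset_s": [0.0, 0.5, 0.0, 0.0],
            "subgroup": ["category", "category", "choice", "choice"],
            "epoch": ["stimulus", "stimulus", "response", "response"],
        })
        d = DesignMatrix(X=X, columns=cols, frame_rate_hz=15.0,
                         trial_starts=np.array([0]), frames_per_trial=200,
                         trial_index=pd.DataFrame({"trial_id": [0]}))
        mv, per = max_vif(d, mode="across_epochs")
        assert np.isinf(mv)
        worst = max(per, key=per.get)
        assert worst[0] in ("a", "c")  # offending column identified

    def test_session_design_within_bound(self, engine):
        mv, _ = max_vif(engine.design)
        assert np.isfinite(mv)
        assert mv <= 5.0

    def test_across_sets_mode_reports_structural_collinearity(self, engine):
        """Complete one-hot event sets are exactly collinear through their
        sums; the literal all-other-columns pool must expose that."""
        mv, _ = max_vif(engine.design, mode="across_sets")
        assert mv > 100 or np.isinf(mv)
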