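"""VAR fitting, BIC order selection, and conditional Granger causality."""

import numpy as np
import pytest

from neurochip.granger import (
    VARModel,
    bic,
    conditional_gc,
    fit_var,
    gc_graph,
    permutation_pvalue,
    segment_trials,
    select_order,
)
from neurochip.synthetic import gen_var


def bivariate_system(n_trials=50, trial_length=500, seed=0, coupling=0.9):
    """y_t = coupling * x_{t-1} + eps; x white noise."""
    coefs = np.zeros((1, 2, 2))
    coefs[0, 1, 0] = coupling
    return gen_var(coefs, np.eye(2), n_trials, trial_length, seed=seed)


class TestFitVar:
    def test_white_noise_coefficients_are_null(self):
        trials = gen_var(np.zeros((1, 3, 3)), np.eye(3), 20, 500, seed=1)
        model = fit_var(trials, p=2)
        se = 1.0 / np.sqrt(model.n_obs)
        assert np.max(np.abs(model.coefficients)) < 3 * se * 3

    def test_var1_coefficient_recovered(self):
        coefs = np.zeros((1, 2, 2))
        coefs[0, 1, 0] = 0.9
        trials = gen_var(coefs, np.eye(2), 100, 1000, seed=2)
        model = fit_var(trials, p=1)
        assert model.coefficients[0, 1, 0] == pytest.approx(0.9, abs=0.02)
        assert model.coefficients[0, 0, 1] == pytest.approx(0.0, abs=0.02)

    def test_order_zero_is_mean_model_with_sample_covariance(self):
        rng = np.random.default_rng(3)
        trials = rng.standard_normal((4, 2, 100))
        model = fit_var(trials, p=0)
        stacked = trials.transpose(0, 2, 1).reshape(-1, 2)
        assert np.allclose(model.intercept, stacked.mean(axis=0))
        centered = stacked - stacked.mean(axis=0)
        assert np.allclose(model.residual_covariance,
                           centered.T @ centered / len(stacked))

    def test_residual_covariance_is_symmetric_psd(self):
        trials = bivariate_system(20, 200, seed=4)
        sigma = fit_var(trials, p=2).residual_covariance
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-12

    def test_matches_statsmodels_on_single_trial(self):
        pytest.importorskip("statsmodels")
        from statsmodels.tsa.api import VAR

        trials = bivariate_system(1, 2000, seed=5)
        model = fit_var(trials, p=2)
        res = VAR(trials[0].T).fit(maxlags=2, trend="c")
        # statsmodels coefs: (lags*m + 1, m); ours: (p, m, m)
        for lag in range(2):
            theirs = res.coefs[lag]
            assert np.allclose(model.coefficients[lag], theirs, atol=1e-8)
        assert np.allclose(model.intercept, res.params[0], atol=1e-8)

    def test_rank_deficiency_suggests_smaller_order(self):
        constant = np.zeros((2, 2, 50))
        with pytest.raises(np.linalg.LinAlgError, match="smaller"):
            fit_var(constant, p=3)


class TestOrderSelection:
    def test_bic_penalty_strictly_increasing_in_order(self):
        sigma = np.eye(2)
        bics = [
            bic(VARModel(order=p, coefficients=np.zeros((p, 2, 2)),
                         intercept=np.zeros(2), residual_covariance=sigma,
                         n_obs=1000))
            for p in range(1, 6)
        ]
        assert np.all(np.diff(bics) > 0)

    def test_white_noise_selects_smallest_order(self):
        trials = gen_var(np.zeros((1, 2, 2)), np.eye(2), 10, 500, seed=6)
        assert select_order(trials, p_range=range(1, 8)) == 1

    def test_var3_order_recovered(self):
        coefs = np.zeros((3, 2, 2))
        coefs[0] = [[0.4, 0.0], [0.2, 0.3]]
        coefs[2] = [[0.0, 0.25], [0.0, 0.3]]
        hits = 0
        for seed in range(5):
            trials = gen_var(coefs, np.eye(2), 10, 500, seed=seed)
            hits += select_order(trials, p_range=range(1, 8)) == 3
        assert hits >= 4

    def test_plateau_rule_picks_smallest_order_near_minimum(self):
        trials = gen_var(np.zeros((1, 2, 2)), np.eye(2), 10, 500, seed=7)
        p_arg = select_order(trials, p_range=range(1, 8), rule="argmin")
        p_pla = select_order(trials, p_range=range(1, 8), rule="plateau",
                             plateau_tol=0.05)
        assert p_pla <= p_arg


class TestConditionalGC:
    def test_analytic_bivariate_magnitude(self):
        trials = bivariate_system(100, 1000, seed=8)
        mag = conditional_gc(trials, source=0, target=1, p=1)
        assert mag == pytest.approx(np.log(1.81), rel=0.05)

    def test_reverse_direction_is_null(self):
        trials = bivariate_system(100, 1000, seed=9)
        assert conditional_gc(trials, source=1, target=0, p=1) < 0.01

    def test_magnitude_invariant_to_channel_rescaling(self):
        trials = bivariate_system(30, 400, seed=10)
        scaled = trials * np.array([13.0, 0.07])[None, :, None]
        a = conditional_gc(trials, 0, 1, p=1)
        b = conditional_gc(scaled, 0, 1, p=1)
        assert a == pytest.approx(b, rel=1e-6)

    def test_source_in_conditioning_set_rejected(self):
        trials = bivariate_system(5, 100, seed=11)
        with pytest.raises(ValueError, match="conditioning"):
            conditional_gc(trials, 0, 1, conditioning=[0], p=1)

    def test_permutation_observed_matches_direct_computation(self):
        trials = bivariate_system(30, 300, seed=12)
        direct = conditional_gc(trials, 0, 1, p=1)
        observed, _ = permutation_pvalue(trials, 0, 1, [], p=1,
                                         n_permutations=10, seed=0)
        assert observed == pytest.approx(direct, rel=1e-9)

    def test_chain_mediation_removed_by_conditioning(self):
        # x -> y -> z: conditioning on y explains z's dependence on x
        coefs = np.zeros((1, 3, 3))
        coefs[0, 1, 0] = 0.8
        coefs[0, 2, 1] = 0.8
        trials = gen_var(coefs, np.eye(3), 100, 200, seed=13)
        _, p_uncond = permutation_pvalue(trials, 0, 2, [], p=2,
                                         n_permutations=200, seed=1)
        _, p_cond = permutation_pvalue(trials, 0, 2, [1], p=2,
                                       n_permutations=200, seed=1)
        assert p_uncond <= 0.01
        assert p_cond > 0.01


class TestGCGraph:
    def test_planted_edges_recovered_and_no_self_edges(self):
        coefs = np.zeros((1, 4, 4))
        true_edges = {(0, 1), (1, 2), (0, 3)}
        for s, t in true_edges:
            coefs[0, t, s] = 0.7
        trials = gen_var(coefs, np.eye(4), 80, 250, seed=14)
        graph = gc_graph(trials, p=1, alpha=0.01, n_permutations=1500, seed=0)
        assert set(graph.significant_edges()) == true_edges
        assert all(e.source != e.target for e in graph.edges)

    def test_independent_channels_rarely_yield_edges(self):
        trials = gen_var(np.zeros((1, 3, 3)), np.eye(3), 40, 200, seed=15)
        graph = gc_graph(trials, p=1, alpha=0.05, n_permutations=300, seed=2)
        assert len(graph.significant_edges()) <= 1

    def test_graph_exports(self, tmp_path):
        trials = bivariate_system(20, 200, seed=16)
        graph = gc_graph(trials, p=1, n_permutations=50, seed=3,
                         channel_names=("x", "y"), behavior="demo")
        df = graph.to_frame()
        assert set(df.columns) >= {"source", "target", "magnitude", "p"}
        graph.write_graphml(tmp_path / "g.graphml")
        assert (tmp_path / "g.graphml").stat().st_size > 0


class TestSegmentTrials:
    def test_contiguous_equal_segments(self):
        chans = np.arange(20, dtype=float).reshape(1, 20)
        trials = segment_trials(np.vstack([chans, chans * 10]), n_trials=4)
        assert trials.shape == (4, 2, 5)
        assert trials[1, 0].tolist() == [5, 6, 7, 8, 9]
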