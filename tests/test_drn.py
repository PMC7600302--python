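"""Wide&Deep regressor: features, architecture arithmetic, training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mieff
from mieff.containers import CONFIG_2CH
from mieff.drn import (DeepRegressionNetwork, SubjectData, build_drn,
                       build_inputs, evaluate, linear_baseline, loo_evaluate,
                       moment_features, psi_map)


class TestMomentFeatures:
    def test_degenerate_constant_window(self):
        x = np.full(160, 3.0)
        np.testing.assert_allclose(moment_features(x, 160.0), [3, 3, 0, 3, 3])

    def test_window_arithmetic(self):
        feats = moment_features(np.arange(320.0), 160.0)
        assert feats.size == 15  # 3 windows x 5 moments

    def test_hand_computed_moments(self):
        feats = moment_features(np.array([1.0, 2.0, 3.0, 4.0]), 4.0)
        np.testing.assert_allclose(feats, [2.5, 2.5, 1.25, 1, 4])

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            moment_features(np.zeros(10), 160.0)


class TestBuildInputs:
    def test_baseline_window_arithmetic(self, small_trials):
        stack = build_inputs(SubjectData(trials=small_trials), "baseline", CONFIG_2CH)
        # 24 trials x 2 s at 160 Hz -> 48 s -> 95 windows -> 475 features
        assert stack.shape == (2, 475)

    def test_channel_order_is_part_of_the_contract(self, small_trials):
        from mieff.containers import ChannelConfig
        a = build_inputs(SubjectData(trials=small_trials), "baseline",
                         ChannelConfig("a", ("C3", "C4")))
        b = build_inputs(SubjectData(trials=small_trials), "baseline",
                         ChannelConfig("b", ("C4", "C3")))
        assert not np.allclose(a, b)
        np.testing.assert_allclose(a[0], b[1])

    def test_erds_source_shape(self, small_trials):
        stack = build_inputs(SubjectData(trials=small_trials), "erds", CONFIG_2CH,
                             bands=("mu",))
        # two 2 s curves at 160 Hz concatenated -> 640 samples -> 7 windows
        assert stack.shape == (2, 35)

    def test_missing_resting_rejected(self, small_trials):
        with pytest.raises(ValueError):
            build_inputs(SubjectData(trials=small_trials), "resting", CONFIG_2CH)


class TestArchitecture:
    @pytest.mark.parametrize("d,c,h,ct,t2", [(15, 2, 23, 46, 23),
                                             (15, 6, 23, 138, 69)])
    def test_printed_sizes(self, d, c, h, ct, t2):
        arch = build_drn(d, c)
        assert (arch.h, arch.ct_size, arch.theta2_size, arch.theta3_size) == \
            (h, ct, t2, 1)

    def test_scalar_variant_sizes(self):
        arch = build_drn(100, 6, scalar_variant=True)
        assert (arch.h, arch.theta2_size) == (2, 1)

    @given(st.integers(1, 400), st.integers(1, 8))
    @settings(max_examples=50, deadline=None)
    def test_ceiling_formulas_hold_everywhere(self, d, c):
        arch = build_drn(d, c)
        assert arch.h == int(np.ceil(1.5 * d))
        assert arch.ct_size == arch.h * c
        assert arch.theta2_size == int(np.ceil(0.5 * arch.h * c))


class TestTraining:
    def test_constant_targets_fit_to_constant(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(10, 2, 5))
        res = DeepRegressionNetwork(feats, np.full(10, 0.7)).fit(epochs=2000, seed=0)
        assert np.abs(res.xi_star - 0.7).max() <= 0.02

    def test_linear_target_recovery(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(50, 2, 10))
        target = 0.3 * feats.mean(axis=(1, 2)) + 0.6
        res = DeepRegressionNetwork(feats, target).fit(epochs=2000, seed=0)
        assert res.spearman() >= 0.95

    def test_same_seed_identical_parameters(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(8, 2, 6))
        y = rng.uniform(size=8)
        r1 = DeepRegressionNetwork(feats, y).fit(epochs=200, seed=3)
        r2 = DeepRegressionNetwork(feats, y).fit(epochs=200, seed=3)
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])

    def test_nonfinite_input_rejected(self):
        feats = np.zeros((5, 1, 2))
        feats[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            DeepRegressionNetwork(feats, np.zeros(5))

    def test_xi_star_permutes_with_subjects(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(9, 2, 4))
        y = rng.uniform(size=9)
        res = DeepRegressionNetwork(feats, y).fit(epochs=300, seed=0)
        perm = rng.permutation(9)
        np.testing.assert_allclose(res.predict(feats[perm]), res.xi_star[perm],
                                   atol=1e-10)

    def test_scalar_variant_preserves_rank_order(self):
        xi = np.linspace(0, 1, 20)
        y = 0.5 + 0.4 * xi
        res = DeepRegressionNetwork(xi, y).fit(epochs=1500, seed=0)
        assert evaluate(res.xi_star, xi).r == pytest.approx(1.0)

    def test_summary_mentions_architecture(self):
        rng = np.random.default_rng(5)
        res = DeepRegressionNetwork(rng.normal(size=(6, 2, 15)),
                                    rng.uniform(size=6)).fit(epochs=50, seed=0)
        text = res.summary()
        assert "23" in text and "46" in text  # h and concat width for d=15, C=2


class TestPsiMap:
    def test_rank_one_matrix_matches_plain_mean(self):
        subj = np.linspace(0.5, 0.9, 10)
        V = np.outer(subj, np.ones(4))
        scores = psi_map(V, "pca1")
        assert evaluate(scores, V.mean(axis=1)).r == pytest.approx(1.0)

    def test_identical_columns_reduce_to_that_column(self):
        col = np.linspace(0.4, 0.9, 8)
        V = np.tile(col[:, None], (1, 4))
        out = psi_map(V, "mean")
        np.testing.assert_allclose(out, col)

    def test_inverse_variance_weighting(self):
        rng = np.random.default_rng(0)
        n = 400
        V = np.column_stack([
            rng.normal(0.7, 0.1, n),
            rng.normal(0.7, 0.2, n),
            rng.normal(0.7, 0.1, n),
            rng.normal(0.7, 0.1, n),
        ])
        out = psi_map(V, "mean")
        # recover the implied weights by least squares; the noisier column
        # (variance 4x) should carry ~1/4 the weight of the quiet ones
        w, *_ = np.linalg.lstsq(V - V.mean(0), out - out.mean(), rcond=None)
        assert w[1] == pytest.approx(w[0] / 4, rel=0.15)


class TestEvaluate:
    def test_perfectly_monotone(self):
        assert evaluate(np.arange(5.0), np.arange(5.0) ** 2).r == pytest.approx(1.0)

    def test_reversed_monotone(self):
        assert evaluate(np.arange(5.0), -np.arange(5.0)).r == pytest.approx(-1.0)

    def test_single_swap_rank_formula(self):
        r = evaluate(np.array([1, 2, 3, 4, 5.0]), np.array([1, 2, 3, 5, 4.0])).r
        assert r == pytest.approx(0.9)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning):
            res = evaluate(np.ones(5), np.arange(5.0))
        assert res.degenerate and np.isnan(res.r)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        xi = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = evaluate(xi, y).r
        r2 = evaluate(np.exp(2 * xi) + 5, y).r
        assert r1 == pytest.approx(r2)


class TestLinearBaseline:
    def test_identity_indicator(self):
        y = np.linspace(0.5, 0.9, 10)
        assert linear_baseline(y, y).r == pytest.approx(1.0)

    def test_independent_noise_rarely_correlates(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = linear_baseline(rng.normal(size=50), rng.normal(size=50)).r
            hits += abs(r) < 0.3
        assert hits >= 19


class TestLOO:
    def test_fit_count_and_mode(self):
        rng = np.random.default_rng(0)
        xi = np.linspace(0, 1, 12) + rng.normal(0, 0.01, 12)
        y = 0.5 + 0.4 * xi
        res = loo_evaluate(xi, y, epochs=400, seed=0)
        assert res.mode == "loo"
        assert res.diagnostics["n_fits"] == 12
        assert res.predictions.size == 12

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loo_evaluate(np.arange(3.0), np.arange(3.0))
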