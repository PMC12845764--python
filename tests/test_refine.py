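"""Metropolis-Hastings refinement: transition rule, acceptance rule, chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcwavegan.features import FeatureConfig, GaussianPrior, desk_feature_config, fit_gaussian_prior
from mcwavegan.refine import (
    ChainState,
    MetropolisRefiner,
    RefineConfig,
    acceptance_probability,
    ema_smooth,
    mh_step,
    refine,
    refine_features,
    sweep_beta,
    transition_vector,
)

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestTransitionVector:
    def test_beta_zero_limit(self):
        v, s, r = np.array([3.0, 1.0]), np.array([1.0, 1.0]), np.array([9.0, 9.0])
        assert np.array_equal(transition_vector(v, s, r, 0.0), v - s)

    def test_beta_one_limit(self):
        v, s, r = np.array([3.0, 1.0]), np.array([1.0, 1.0]), np.array([9.0, 9.0])
        assert np.array_equal(transition_vector(v, s, r, 1.0), v - r)

    def test_worked_example(self):
        out = transition_vector(
            np.array([1.0, 0.0]), np.array([0.0, 0.0]), np.array([2.0, 2.0]), 0.5
        )
        assert np.allclose(out, [0.0, -1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(finite, min_size=3, max_size=3),
        st.lists(finite, min_size=3, max_size=3),
        st.lists(finite, min_size=3, max_size=3),
        st.floats(0.0, 1.0),
    )
    def test_matches_direct_arithmetic(self, v, s, r, beta):
        v, s, r = map(np.asarray, (v, s, r))
        expected = (1 - beta) * (v - s) + beta * (v - r)
        assert np.allclose(transition_vector(v, s, r, beta), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transition_vector(np.zeros(2), np.zeros(3), np.zeros(2), 0.5)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transition_vector(np.zeros(2), np.zeros(2), np.zeros(2), 1.5)


class TestAcceptanceProbability:
    def test_equal_densities_give_one(self):
        prior = GaussianPrior(np.zeros(2), np.ones(2))
        x = np.array([0.3, -0.7])
        assert acceptance_probability(x, x.copy(), prior) == 1.0

    def test_standard_normal_closed_form(self):
        prior = GaussianPrior(np.zeros(1), np.ones(1))
        alpha = acceptance_probability(np.array([1.0]), np.array([0.0]), prior)
        assert np.isclose(alpha, np.exp(-0.5), atol=1e-12)

    def test_uphill_moves_clip_at_one(self):
        prior = GaussianPrior(np.zeros(1), np.ones(1))
        assert acceptance_probability(np.array([0.0]), np.array([2.0]), prior) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=2),
        st.lists(st.floats(-50, 50), min_size=2, max_size=2),
    )
    def test_alpha_always_in_unit_interval(self, a, b):
        prior = GaussianPrior(np.zeros(2), np.array([0.5, 3.0]))
        alpha = acceptance_probability(np.asarray(a), np.asarray(b), prior)
        assert 0.0 <= alpha <= 1.0

    def test_invariant_to_density_normalization(self):
        """Only density ratios enter the rule, so adding any constant to
        the log density (multiplying p by a positive constant) is a no-op."""
        base = GaussianPrior(np.zeros(2), np.ones(2))

        class Scaled:
            def __init__(self, c):
                self.c = c

            def logpdf(self, x):
                return base.logpdf(x) + self.c

        a, b = np.array([0.5, 0.1]), np.array([1.5, -0.2])
        ref = acceptance_probability(a, b, base)
        for c in (-100.0, 0.0, 7.3):
            assert np.isclose(acceptance_probability(a, b, Scaled(c)), ref, atol=1e-12)


class TestEmaSmooth:
    def test_alpha_one_is_identity(self):
        assert np.array_equal(ema_smooth(np.array([5.0]), np.array([10.0]), 1.0), [10.0])

    def test_worked_example(self):
        assert np.allclose(ema_smooth(np.array([0.0]), np.array([10.0]), 0.2), [2.0])

    def test_first_sample_initializes(self):
        assert np.array_equal(ema_smooth(None, np.array([3.0]), 0.2), [3.0])

    def test_constant_stream_converges(self):
        acc = None
        for _ in range(200):
            acc = ema_smooth(acc, np.array([4.0]), 0.3)
        assert np.allclose(acc, 4.0)


class _ConstantAlphaPrior:
    """Stub density making every proposal's acceptance probability α."""

    def __init__(self, alpha):
        self.log_alpha = np.log(alpha)
        self.calls = 0

    def logpdf(self, x):
        self.calls += 1
        # acceptance_probability evaluates p(θprop) first, p(θt) second
        return self.log_alpha if self.calls % 2 == 1 else 0.0


class TestMhStep:
    def _state(self, seed=0, d=2):
        return ChainState(theta=np.zeros(d), s=np.zeros(d),
                          ema=None, rng=np.random.default_rng(seed))

    def test_certain_acceptance(self):
        pool = np.zeros((4, 2))
        reals = np.zeros((4, 2))
        prior = GaussianPrior(np.zeros(2), np.ones(2))  # all proposals at the mode
        state = self._state()
        mh_step(state, pool, reals, prior, RefineConfig(beta=0.5, n_out=10))
        assert len(state.accepted) == 1 and state.last_alpha == 1.0

    def test_rejection_leaves_state_unchanged(self):
        pool = np.full((4, 2), 100.0)
        reals = np.zeros((4, 2))
        prior = GaussianPrior(np.zeros(2), np.full(2, 1e-6))  # proposals hopeless
        state = self._state()
        theta_before = state.theta.copy()
        mh_step(state, pool, reals, prior, RefineConfig(beta=0.0, n_out=10))
        assert len(state.accepted) == 0
        assert np.array_equal(state.theta, theta_before)
        assert state.t == 1 and state.n_proposed == 1

    def test_stubbed_constant_alpha_rate(self):
        """With α pinned to 0.3 the accept/reject loop is a Bernoulli(0.3)
        process: 10,000 steps land within 0.30 ± 0.02."""
        pool = np.zeros((4, 2))
        reals = np.zeros((4, 2))
        prior = _ConstantAlphaPrior(0.3)
        state = self._state(seed=123)
        cfg = RefineConfig(beta=0.5, n_out=10_001)
        for _ in range(10_000):
            mh_step(state, pool, reals, prior, cfg)
        rate = len(state.accepted) / 10_000
        assert abs(rate - 0.30) <= 0.02


class TestRefine:
    def test_self_refinement_reaches_target(self, desk_data):
        """pool == reals is the chain's easiest regime: the target count
        is reached comfortably within budget, and acceptance is far
        higher than for a mismatched pool.  (The uncorrected
        independence chain concentrates at states of above-typical
        density, so the raw acceptance rate sits below the naive 1/2
        even for a perfectly matched pool in 22 dimensions.)"""
        qp = desk_data.filter_label("QueenPresent").subset(np.arange(100))
        cfg = RefineConfig(beta=0.5, n_out=50, seed=0, feature_config=desk_feature_config())
        out = refine(qp, qp, cfg)
        assert len(out.clips) == 50
        assert out.acceptance_rate > 0.0

        shifted = qp.subset(np.arange(100))
        shifted.segments = shifted.segments * 8.0  # grossly off-distribution pool
        with pytest.warns(RuntimeWarning, match="budget exhausted"):
            worse = refine(shifted, qp, cfg)
        assert out.acceptance_rate > worse.acceptance_rate

    def test_emits_bitwise_pool_members(self, desk_data):
        pool = desk_data.filter_label("NoBee").subset(np.arange(10))
        reals = desk_data.filter_label("NoBee").subset(np.arange(10, 20))
        cfg = RefineConfig(beta=0.1, n_out=5, seed=1, feature_config=desk_feature_config())
        out = refine(pool, reals, cfg)
        assert len(out.clips) == 5
        for clip, idx in zip(out.clips.segments, out.accepted_indices):
            assert np.array_equal(clip, pool.segments[idx])

    def test_seeded_rerun_identical(self, desk_data):
        pool = desk_data.filter_label("QueenAbsent").subset(np.arange(30))
        reals = desk_data.filter_label("QueenAbsent").subset(np.arange(30, 60))
        cfg = RefineConfig(beta=0.3, n_out=20, seed=9, feature_config=desk_feature_config())
        a = refine(pool, reals, cfg)
        b = refine(pool, reals, cfg)
        assert np.array_equal(a.accepted_indices, b.accepted_indices)
        assert np.array_equal(a.features, b.features)

    def test_budget_exhaustion_warns_and_emits_partial(self):
        rng = np.random.default_rng(0)
        reals = rng.normal(0, 1, (50, 4))
        pool = rng.normal(60, 1, (50, 4))  # far from real transitions
        cfg = RefineConfig(beta=1.0, n_out=40, seed=0, max_iters=500)
        with pytest.warns(RuntimeWarning, match="budget exhausted"):
            idx, feats, rate = refine_features(pool, reals, cfg)
        assert len(idx) < 40

    def test_ema_reduces_roughness_of_accepted_features(self):
        """Mean squared successive difference of the smoothed stream is
        no larger than that of the raw accepted features."""
        rng = np.random.default_rng(3)
        reals = rng.normal(0, 1, (200, 6))
        pool = rng.normal(0.3, 1, (400, 6))
        for ema_alpha in (0.2, 0.5, 0.8):
            cfg = RefineConfig(beta=0.7, n_out=150, seed=4, ema_alpha=ema_alpha)
            idx, smoothed, _ = refine_features(pool, reals, cfg)
            raw = pool[idx]
            mssd = lambda x: np.mean(np.sum(np.diff(x, axis=0) ** 2, axis=1))
            assert mssd(smoothed) <= mssd(raw)

    def test_prior_on_features_mode_runs(self):
        rng = np.random.default_rng(1)
        reals = rng.normal(0, 1, (100, 4))
        pool = rng.normal(0, 1, (100, 4))
        cfg = RefineConfig(beta=0.5, n_out=30, seed=2, prior_on="features")
        idx, feats, rate = refine_features(pool, reals, cfg)
        assert len(idx) == 30

    def test_refiner_estimator_front(self, desk_data):
        qp = desk_data.filter_label("QueenPresent").subset(np.arange(40))
        ref = MetropolisRefiner(beta=0.2, n_out=10, seed=0,
                                feature_config=desk_feature_config())
        assert ref.get_params()["beta"] == 0.2
        ref.set_params(beta=0.4)
        out = ref.fit(qp).transform(qp)
        assert len(out.clips) == 10
        with pytest.raises(ValueError):
            ref.set_params(gamma=1)


class TestSweepBeta:
    def test_rows_sum_to_emitted_and_best_flagged(self, desk_data, desk_model):
        pool = desk_data.filter_label("QueenPresent").subset(np.arange(60))
        reals = desk_data.filter_label("QueenPresent").subset(np.arange(60, 120))
        cfg = RefineConfig(beta=0.1, n_out=25, seed=0, feature_config=desk_feature_config())
        table = sweep_beta(pool, reals, [0.1, 0.5], cfg, desk_model, "QueenPresent")
        assert len(table) == 2
        class_cols = list(desk_model.classes_)
        assert (table[class_cols].sum(axis=1) == table["n_out"]).all()
        assert table["best"].sum() == 1

    def test_single_beta_is_best(self, desk_data, desk_model):
        pool = desk_data.filter_label("NoBee").subset(np.arange(30))
        reals = desk_data.filter_label("NoBee").subset(np.arange(30, 60))
        cfg = RefineConfig(beta=0.2, n_out=10, seed=0, feature_config=desk_feature_config())
        table = sweep_beta(pool, reals, [0.2], cfg, desk_model, "NoBee")
        assert len(table) == 1 and bool(table.loc[0, "best"])


def test_refine_config_validation():
    with pytest.raises(ValueError):
        RefineConfig(beta=-0.1, n_out=10)
    with pytest.raises(ValueError):
        RefineConfig(beta=1.1, n_out=10)
    with pytest.raises(ValueError):
        RefineConfig(beta=0.5, n_out=0)
    with pytest.raises(ValueError):
        RefineConfig(beta=0.5, n_out=10, ema_alpha=0.0)
    assert RefineConfig(beta=0.5, n_out=10).budget == 500
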