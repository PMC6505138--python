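import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import codonmix as cm
from codonmix.mixture import _MergeEngine, scramble_permutation


class TestTheoreticalB:
    def test_gzb_equal_exponential_bound(self):
        # two equally weighted compartments, each with sd = mean = 1/64
        assert cm.theoretical_B(0.5, 1 / 64, 1 / 64) == pytest.approx(
            np.sqrt(63 * 0.5 * (1 / 64) ** 2), abs=1e-15)

    def test_pure_gaussian_endpoint(self):
        assert cm.theoretical_B(1.0, 0.0081, 0.0207) == pytest.approx(
            np.sqrt(63) * 0.0081, abs=1e-15)

    def test_pure_empirical_endpoint(self):
        assert cm.theoretical_B(0.0, 0.0081, 0.0207) == pytest.approx(
            np.sqrt(63) * 0.0207, abs=1e-15)

    @given(alpha=st.floats(0.0, 0.8))
    def test_decreasing_in_alpha_below_crossover(self, alpha):
        s1, s2 = 0.0081, 0.0207
        # decreasing while alpha <= s2^2/(s1^2+s2^2) ~ 0.867
        assert cm.theoretical_B(alpha + 0.01, s1, s2) < cm.theoretical_B(alpha, s1, s2)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            cm.theoretical_B(1.5, 0.01, 0.01)
        with pytest.raises(ValueError):
            cm.theoretical_B(0.5, -0.01, 0.01)


class TestScramble:
    def test_swaps_give_valid_permutation(self):
        rng = np.random.default_rng(0)
        perm = scramble_permutation(rng, swap_cycles=10_000)
        assert sorted(perm) == list(range(64))

    def test_methods_both_near_uniform(self):
        # position of rank 0 should be ~uniform under both scramblers
        counts = {m: np.zeros(64) for m in ("swaps", "permutation")}
        for m in counts:
            rng = np.random.default_rng(123)
            for _ in range(2000):
                counts[m][scramble_permutation(rng, 200, m)[0]] += 1
        for m, c in counts.items():
            chi2 = ((c - 2000 / 64) ** 2 / (2000 / 64)).sum()
            assert chi2 < 120  # df=63, p~1e-5 cutoff


class TestMerge:
    def test_alpha_one_returns_comp1(self, comp1, comp2):
        rng = np.random.default_rng(0)
        seq = cm.merge_once(comp1, comp2, 1.0, rng)
        assert np.allclose(seq.values, comp1.values, atol=1e-15)

    def test_alpha_zero_returns_comp2(self, comp1, comp2):
        rng = np.random.default_rng(0)
        seq = cm.merge_once(comp1, comp2, 0.0, rng)
        assert np.allclose(seq.values, comp2.values, atol=1e-15)

    @given(alpha=st.floats(0.0, 1.0), seed=st.integers(0, 1000))
    def test_sums_to_one(self, comp1, comp2, alpha, seed):
        rng = np.random.default_rng(seed)
        seq = cm.merge_once(comp1, comp2, alpha, rng, swap_cycles=500)
        assert seq.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(seq.values) <= 0)

    def test_mean_b_squared_follows_variance_composition(self, comp1, comp2):
        # random rank pairing makes the compartment deviations
        # independent, so squared biases add in quadrature
        alpha = 0.5
        rng = np.random.default_rng(11)
        b2 = np.array([cm.bias(cm.merge_once(comp1, comp2, alpha, rng,
                                             scramble="permutation")) ** 2
                       for _ in range(400)])
        expected = 63 * (alpha ** 2 * comp1.sd ** 2 + (1 - alpha) ** 2 * comp2.sd ** 2)
        se = b2.std(ddof=1) / np.sqrt(len(b2))
        assert abs(b2.mean() - expected) < 3 * se


class TestMeanMerged:
    def test_alpha_one_has_zero_scatter(self, comp1, comp2):
        mean, rms = cm.mean_merged(comp1, comp2, 1.0, trials=20, seed=0)
        assert rms == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(mean.values, comp1.values, atol=1e-15)

    def test_reference_scatter_scale(self, comp1, comp2):
        # individual randomizations scatter about the mean curve with
        # rms of order 1e-3 at alpha = 0.5
        _, rms = cm.mean_merged(comp1, comp2, 0.5, trials=100, seed=0)
        assert 3e-4 < rms < 3e-3

    def test_mean_is_non_increasing(self, comp1, comp2):
        mean, _ = cm.mean_merged(comp1, comp2, 0.37, trials=30, seed=2)
        assert np.all(np.diff(mean.values) <= 0)
        assert mean.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_requires_two_trials(self, comp1, comp2):
        with pytest.raises(ValueError):
            cm.mean_merged(comp1, comp2, 0.5, trials=1)


class TestFit:
    def test_recovers_known_alpha(self, comp1, comp2):
        target, _ = cm.mean_merged(comp1, comp2, 0.6, trials=100, seed=5)
        res = cm.fit_alpha(target, comp1, comp2, seed=9)
        assert res.alpha_hat == pytest.approx(0.60, abs=0.02)
        assert res.rms_residual < 5e-4

    def test_endpoint_recovery_comp1(self, comp1, comp2):
        res = cm.fit_alpha(cm.OrderedFrequencySequence(comp1.values), comp1, comp2, seed=1)
        assert res.alpha_hat >= 0.98

    def test_endpoint_recovery_comp2(self, comp1, comp2):
        res = cm.fit_alpha(cm.OrderedFrequencySequence(comp2.values), comp1, comp2, seed=1)
        assert res.alpha_hat <= 0.02

    def test_objective_deterministic_in_seed(self, comp1, comp2):
        target, _ = cm.mean_merged(comp1, comp2, 0.4, trials=50, seed=3)
        r1 = cm.fit_alpha(target, comp1, comp2, seed=17)
        r2 = cm.fit_alpha(target, comp1, comp2, seed=17)
        assert r1.alpha_hat == r2.alpha_hat
        assert r1.rms_residual == r2.rms_residual

    def test_predicted_b_consistent_with_closed_form(self, comp1, comp2):
        target, _ = cm.mean_merged(comp1, comp2, 0.7, trials=50, seed=3)
        res = cm.fit_alpha(target, comp1, comp2, seed=4)
        assert res.predicted_B == pytest.approx(
            cm.theoretical_B(res.alpha_hat, comp1.sd, comp2.sd), abs=1e-12)

    def test_results_object_surface(self, comp1, comp2):
        model = cm.CodonMixture(comp1.values, comp1, comp2, trials=30, seed=0,
                                genome_id="demo")
        res = model.fit(grid_step=0.05)
        assert isinstance(res, cm.MixtureFitResults)
        assert res.residuals.shape == (64,)
        assert res.rms_residual == pytest.approx(
            np.sqrt(np.mean(res.residuals ** 2)), abs=1e-15)
        text = res.summary()
        assert "alpha" in text and "demo" in text

    def test_invalid_grid_step(self, comp1, comp2):
        with pytest.raises(ValueError):
            cm.CodonMixture(comp1.values, comp1, comp2).fit(grid_step=0.5)


def test_engine_common_random_numbers(comp1, comp2):
    e = _MergeEngine(comp1, comp2, trials=10, seed=0)
    m1, _ = e.mean_sequence(0.3)
    m2, _ = e.mean_sequence(0.3)
    assert np.array_equal(m1, m2)
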