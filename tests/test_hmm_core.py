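"""Exactness of the constrained forward/Viterbi/forward-backward
recursions, checked against brute-force path enumeration."""

import numpy as np
import pytest

from _oracles import (
    brute_loglik,
    brute_posteriors,
    brute_viterbi,
    random_hmm_params,
    random_segment,
)
from sshmm import hmm
from sshmm.hmm import EmissionParams, Observations, forward_loglik


def single_obs(steps, angles, known=None):
    steps = np.asarray(steps, float)
    angles = np.asarray(angles, float)
    k = None if known is None else [np.asarray(known)]
    return Observations.from_segments([(steps, angles)], k)


class TestForwardLoglik:
    def test_single_fix_known_state(self):
        rng = np.random.default_rng(0)
        params, g = random_hmm_params(rng)
        delta = hmm.stationary_distribution(g)
        obs = single_obs([123.0], [np.nan], [1])
        expected = np.log(delta[1]) + hmm.gamma_logpdf(
            np.array([123.0]), params.step_mean[1], params.step_sd[1]
        )[0]
        assert forward_loglik(params, g, obs) == pytest.approx(expected, abs=1e-10)

    def test_identical_emissions_collapse(self):
        """With equal emissions in all states the path mixture integrates
        to one and the loglik is the sum of per-fix log densities."""
        rng = np.random.default_rng(1)
        _, g = random_hmm_params(rng)
        params = EmissionParams([100.0] * 3, [50.0] * 3, [2.0] * 3)
        steps = rng.gamma(4.0, 25.0, size=12)
        angles = rng.vonmises(0.0, 2.0, size=12)
        obs = single_obs(steps, angles)
        expected = float(
            hmm.gamma_logpdf(steps, 100.0, 50.0).sum()
            + hmm.vonmises_logpdf(angles, 2.0).sum()
        )
        assert forward_loglik(params, g, obs) == pytest.approx(expected, abs=1e-8)

    def test_matches_enumeration_T6(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            params, g = random_hmm_params(rng)
            steps, angles, known = random_segment(rng, 6, params)
            obs = single_obs(steps, angles, known)
            assert forward_loglik(params, g, obs) == pytest.approx(
                brute_loglik(params, g, steps, angles, known), abs=1e-8
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        params, g = random_hmm_params(rng)
        steps, angles, _ = random_segment(rng, 10, params, known_frac=0.0)
        obs = single_obs(steps, angles)
        ll = forward_loglik(params, g, obs)
        perm = np.array([2, 0, 1])
        pp = EmissionParams(
            params.step_mean[perm], params.step_sd[perm], params.kappa[perm]
        )
        gp = g[np.ix_(perm, perm)]
        assert forward_loglik(pp, gp, obs) == pytest.approx(ll, abs=1e-9)

    def test_supervision_never_increases_loglik(self):
        rng = np.random.default_rng(4)
        params, g = random_hmm_params(rng)
        steps, angles, _ = random_segment(rng, 15, params, known_frac=0.0)
        free = forward_loglik(params, g, single_obs(steps, angles))
        for t in range(15):
            for k in range(3):
                known = np.full(15, -1)
                known[t] = k
                constrained = forward_loglik(
                    params, g, single_obs(steps, angles, known)
                )
                assert constrained <= free + 1e-10

    def test_underflow_immune(self):
        """Extreme observations far into a distribution tail stay finite."""
        params = EmissionParams([1.0, 2.0, 3.0], [0.1, 0.1, 0.1], [1.0, 1.0, 1.0])
        g = np.full((3, 3), 1 / 3)
        steps = np.full(50, 5000.0)  # astronomically unlikely under all states
        obs = single_obs(steps, np.full(50, np.nan))
        ll = forward_loglik(params, g, obs)
        assert np.isfinite(ll) and ll < -1e5

    def test_multi_segment_sums(self):
        rng = np.random.default_rng(5)
        params, g = random_hmm_params(rng)
        s1, a1, k1 = random_segment(rng, 5, params)
        s2, a2, k2 = random_segment(rng, 7, params)
        both = Observations.from_segments([(s1, a1), (s2, a2)], [k1, k2])
        sep = forward_loglik(params, g, single_obs(s1, a1, k1)) + forward_loglik(
            params, g, single_obs(s2, a2, k2)
        )
        assert forward_loglik(params, g, both) == pytest.approx(sep, abs=1e-9)


class TestViterbi:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            params, g = random_hmm_params(rng)
            steps, angles, known = random_segment(rng, 6, params)
            obs = single_obs(steps, angles, known)
            np.testing.assert_array_equal(
                hmm.viterbi(params, g, obs),
                brute_viterbi(params, g, steps, angles, known),
            )

    def test_fully_known_returns_labels(self):
        rng = np.random.default_rng(7)
        params, g = random_hmm_params(rng)
        steps, angles, _ = random_segment(rng, 20, params)
        labels = rng.integers(0, 3, size=20)
        obs = single_obs(steps, angles, labels)
        np.testing.assert_array_equal(hmm.viterbi(params, g, obs), labels)


class TestStateProbabilities:
    def test_single_fix_posterior(self):
        rng = np.random.default_rng(8)
        params, g = random_hmm_params(rng)
        delta = hmm.stationary_distribution(g)
        step = 321.0
        dens = np.exp(
            [
                hmm.gamma_logpdf(np.array([step]), params.step_mean[i], params.step_sd[i])[0]
                for i in range(3)
            ]
        )
        expected = delta * dens / (delta * dens).sum()
        post = hmm.state_probabilities(params, g, single_obs([step], [np.nan]))
        np.testing.assert_allclose(post[0], expected, atol=1e-12)

    def test_known_fix_is_indicator(self):
        rng = np.random.default_rng(9)
        params, g = random_hmm_params(rng)
        steps, angles, known = random_segment(rng, 12, params, known_frac=0.5)
        post = hmm.state_probabilities(params, g, single_obs(steps, angles, known))
        for t in np.flatnonzero(known >= 0):
            assert post[t, known[t]] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            params, g = random_hmm_params(rng)
            steps, angles, known = random_segment(rng, 6, params)
            post = hmm.state_probabilities(params, g, single_obs(steps, angles, known))
            np.testing.assert_allclose(
                post, brute_posteriors(params, g, steps, angles, known), atol=1e-8
            )

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        params, g = random_hmm_params(rng)
        steps, angles, known = random_segment(rng, 40, params)
        post = hmm.state_probabilities(params, g, single_obs(steps, angles, known))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_stationary_distribution_fixed_point():
    rng = np.random.default_rng(12)
    g = rng.dirichlet(np.ones(3), size=3)
    pi = hmm.stationary_distribution(g)
    np.testing.assert_allclose(pi @ g, pi, atol=1e-12)
    assert pi.sum() == pytest.approx(1.0)
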