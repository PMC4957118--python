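import math

import numpy as np
import pytest

from protdiff.model_core import (
    GroupObservations,
    HyperParams,
    log_marginal_likelihood_h0,
    log_marginal_likelihood_h1,
    missing_frequencies,
    posterior_h1,
    prior_h1,
    protein_posterior,
)

from _oracles import quad_log_ml_h0, quad_log_ml_h1


class TestMissingFrequencies:
    @pytest.mark.parametrize(
        "n_obs_c,n_mis_c,n_obs_t,n_mis_t,expected",
        [
            (3, 2, 5, 0, (0.4, 0.0)),
            (0, 5, 5, 0, (1.0, 0.0)),
            (4, 1, 2, 3, (0.2, 0.6)),
        ],
    )
    def test_direct_ratios(self, n_obs_c, n_mis_c, n_obs_t, n_mis_t, expected):
        obs = GroupObservations(
            tuple(range(n_obs_c)), tuple(range(n_obs_t)), n_mis_c, n_mis_t
        )
        assert missing_frequencies(obs) == pytest.approx(expected)

    def test_zero_total_samples_rejected(self):
        obs = GroupObservations((), (1.0,), 0, 0)
        with pytest.raises(ValueError):
            missing_frequencies(obs)

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            GroupObservations((np.nan,), (1.0,), 0, 0)


class TestPriorH1:
    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    @pytest.mark.parametrize("phi", [0.1, 1.0, 17.3])
    def test_equal_frequencies_give_exactly_half(self, form, phi):
        for f in (0.0, 0.25, 1.0):
            assert prior_h1(f, f, phi, form) == 0.5

    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    def test_large_phi_limit_is_half(self, form):
        assert prior_h1(0.5, 0.0, 1e6, form) == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    def test_small_phi_limit_is_one(self, form):
        assert prior_h1(0.5, 0.0, 1e-6, form) == pytest.approx(1.0, abs=1e-4)

    def test_polynomial_hand_value(self):
        # p = (1 + 0.4^1) / 2
        assert prior_h1(0.4, 0.0, 1.0, "polynomial") == pytest.approx(0.7)

    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    def test_symmetric_and_bounded(self, form, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 1, 2)
            phi = rng.uniform(0.01, 20)
            p1 = prior_h1(a, b, phi, form)
            assert p1 == prior_h1(b, a, phi, form)
            assert 0.5 <= p1 <= 1.0

    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    def test_monotone_in_frequency_difference(self, form):
        diffs = np.linspace(0, 1, 21)
        p = [prior_h1(d, 0.0, 2.0, form) for d in diffs]
        assert np.all(np.diff(p) >= 0)

    @pytest.mark.parametrize("form", ["polynomial", "exponential"])
    def test_monotone_decreasing_in_phi(self, form):
        phis = np.linspace(0.05, 20, 30)
        p = [prior_h1(0.6, 0.0, phi, form) for phi in phis]
        assert np.all(np.diff(p) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prior_h1(0.5, 0.0, -1.0)
        with pytest.raises(ValueError):
            prior_h1(1.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            prior_h1(0.5, 0.0, 1.0, form="cubic")


class TestMarginalLikelihoods:
    def test_empty_both_groups_gives_zero(self):
        obs = GroupObservations((), (), 3, 3)
        hp = HyperParams()
        assert log_marginal_likelihood_h0(obs, hp) == 0.0
        assert log_marginal_likelihood_h1(obs, hp) == 0.0

    def test_single_observation_matches_quadrature(self):
        # frozen: 2-D quadrature of N(y; mu, s2) N(mu; 0, s2) IG(s2; 2, 1)
        hp = HyperParams(mu0=0.0, alpha=2.0, beta=1.0, kappa=1.0)
        obs = GroupObservations((0.0,), (), 0, 0)
        assert log_marginal_likelihood_h0(obs, hp) == pytest.approx(
            -0.9808292530243305, abs=1e-4
        )

    def test_frozen_six_value_fixture(self):
        # frozen quadrature values for a fixed 3+3 fixture
        y, z = (-0.61, 0.42, 1.10), (0.95, -0.30, 1.77)
        hp = HyperParams(mu0=0.1, alpha=2.5, beta=0.8, tau0=0.0, kappa=1.3)
        obs = GroupObservations(y, z, 0, 0)
        assert log_marginal_likelihood_h0(obs, hp) == pytest.approx(
            -9.239726096493339, abs=1e-4
        )
        assert log_marginal_likelihood_h1(obs, hp) == pytest.approx(
            -9.470712468681889, abs=1e-4
        )

    def test_h1_degenerates_to_h0_at_tiny_kappa(self, rng):
        y = tuple(rng.normal(0, 1, 4))
        z = tuple(rng.normal(0, 1, 5))
        obs = GroupObservations(y, z, 1, 0)
        hp = HyperParams(mu0=0.2, alpha=3.0, beta=1.5, tau0=0.0, kappa=1e-8)
        assert log_marginal_likelihood_h1(obs, hp) == pytest.approx(
            log_marginal_likelihood_h0(obs, hp), abs=1e-3
        )

    def test_one_empty_group_uses_other_group_alone(self, rng):
        z = tuple(rng.normal(0, 1, 4))
        hp = HyperParams(mu0=0.0, alpha=2.0, beta=1.0, kappa=0.7)
        obs = GroupObservations((), z, 5, 1)
        # H0 must equal the single-group pooled marginal
        pooled = GroupObservations(z, (), 0, 0)
        assert log_marginal_likelihood_h0(obs, hp) == pytest.approx(
            log_marginal_likelihood_h0(pooled, hp)
        )
        assert np.isfinite(log_marginal_likelihood_h1(obs, hp))

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_fixture_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(0, 5), rng.integers(1, 5)
        y = rng.normal(0, 1, n1)
        z = rng.normal(0.5, 1, n2)
        hp = HyperParams(
            mu0=rng.uniform(-1, 1),
            alpha=rng.uniform(1.0, 5.0),
            beta=rng.uniform(0.3, 3.0),
            tau0=0.0,
            kappa=rng.uniform(0.1, 3.0),
        )
        obs = GroupObservations(tuple(y), tuple(z), 0, 0)
        assert log_marginal_likelihood_h0(obs, hp) == pytest.approx(
            quad_log_ml_h0(np.concatenate([y, z]), hp), abs=1e-4
        )
        assert log_marginal_likelihood_h1(obs, hp) == pytest.approx(
            quad_log_ml_h1(y, z, hp), abs=1e-4
        )

    def test_bayes_factor_favours_h1_under_large_effect(self):
        hp = HyperParams(mu0=0.0, alpha=2.0, beta=1.0, kappa=5.0)
        wins = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            y = r.normal(0, 1, 5)
            z = r.normal(5.0, 1, 5)  # tau = 5 sigma
            obs = GroupObservations(tuple(y), tuple(z), 0, 0)
            if log_marginal_likelihood_h1(obs, hp) > log_marginal_likelihood_h0(obs, hp):
                wins += 1
        assert wins >= 190

    def test_bayes_factor_neutral_under_null(self):
        hp = HyperParams(mu0=0.0, alpha=2.0, beta=1.0, kappa=5.0)
        bfs = []
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            y = r.normal(0, 1, 5)
            z = r.normal(0, 1, 5)
            obs = GroupObservations(tuple(y), tuple(z), 0, 0)
            bfs.append(
                log_marginal_likelihood_h1(obs, hp) - log_marginal_likelihood_h0(obs, hp)
            )
        assert np.median(bfs) <= 0.0


class TestPosteriorH1:
    def test_uninformative_update(self):
        assert posterior_h1(0.5, -3.0, -3.0) == pytest.approx(0.5)

    def test_degenerate_priors(self):
        assert posterior_h1(1.0, -10.0, 5.0) == 1.0
        assert posterior_h1(0.0, 5.0, -10.0) == 0.0

    def test_hand_value(self):
        # prior 0.7, likelihood ratio 2: 1.4 / 1.7
        assert posterior_h1(0.7, math.log(2.0) - 5.0, -5.0) == pytest.approx(1.4 / 1.7)

    def test_posterior_equals_prior_at_equal_likelihoods(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1)
            l = rng.normal(-5, 3)
            assert posterior_h1(p, l, l) == pytest.approx(p)

    def test_monotone_in_prior_and_likelihood_ratio(self):
        priors = np.linspace(0.01, 0.99, 25)
        posts = [posterior_h1(p, -2.0, -3.0) for p in priors]
        assert np.all(np.diff(posts) > 0)
        ratios = np.linspace(-4, 4, 25)
        posts = [posterior_h1(0.6, -3.0 + r, -3.0) for r in ratios]
        assert np.all(np.diff(posts) > 0)

    def test_numerical_stability_extreme_log_likelihoods(self):
        assert posterior_h1(0.5, -1e4, -2e4) == pytest.approx(1.0)
        assert posterior_h1(0.5, -2e4, -1e4) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            posterior_h1(1.2, 0.0, 0.0)


def test_protein_posterior_end_to_end():
    obs = GroupObservations((0.1, -0.4, 0.8), (1.5, 2.1), 0, 3)
    hp = HyperParams()
    pp = protein_posterior(obs, hp)
    assert 0.5 <= pp.prior_h1 <= 1.0
    assert 0.0 <= pp.posterior_h1 <= 1.0
    assert pp.prior_h1 == pytest.approx(prior_h1(0.0, 0.6, hp.phi))
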