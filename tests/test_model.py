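"""HMM core: emission densities, transition matrices, forward likelihood
against exhaustive path enumeration, and Viterbi decoding."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit

from seasonhmm import (
    DailyStepSeries,
    emission_logdensity,
    forward_loglik,
    gamma_shape_rate,
    transition_matrix,
    viterbi_decode,
    wrapped_cauchy_logpdf,
)
from seasonhmm.model import emission_logb

from conftest import random_params


def random_short_series(rng, T, p_missing=0.3, start_day=None):
    if start_day is None:
        start_day = int(rng.integers(1, 350))
    step = rng.gamma(2.0, 1.0, T)
    turn = rng.uniform(-np.pi, np.pi, T)
    step[rng.random(T) < p_missing] = np.nan
    turn[rng.random(T) < p_missing] = np.nan
    step[0] = np.nan
    turn[: min(2, T)] = np.nan
    return DailyStepSeries(
        "t", 2020, start_day, np.arange(start_day, start_day + T), step, turn
    )


def enumerate_loglik(series, params, basis, swap_labels=False):
    """Brute-force log-likelihood: sum the joint probability over every one
    of the 2^T hidden-state paths."""
    T = len(series)
    phi = params.initial.get(series.start_day)
    # swap_labels relabels the whole model (emissions, transitions, phi)
    # consistently; the marginal likelihood is invariant to the relabeling
    lab = (1, 0) if swap_labels else (0, 1)
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        logp = np.log(phi[lab[path[0]]])
        logp += emission_logdensity(
            series.step_km[0], series.turn_rad[0], lab[path[0]] + 1, params.emissions
        )
        for t in range(1, T):
            gam = transition_matrix(int(series.day[t]), params.transitions, basis)
            logp += np.log(gam[lab[path[t - 1]], lab[path[t]]])
            logp += emission_logdensity(
                series.step_km[t], series.turn_rad[t], lab[path[t]] + 1, params.emissions
            )
        total += np.exp(logp)
    return np.log(total)


class TestGammaShapeRate:
    def test_moment_identities(self):
        assert gamma_shape_rate(2, 1) == (4, 2)
        assert gamma_shape_rate(1, 1) == (1, 1)  # exponential

    def test_round_trip_exact(self, rng):
        for _ in range(20):
            mean, sd = rng.uniform(0.1, 10, 2)
            shape, rate = gamma_shape_rate(mean, sd)
            assert shape / rate == pytest.approx(mean, rel=1e-12)
            assert np.sqrt(shape) / rate == pytest.approx(sd, rel=1e-12)

    def test_nonpositive_rejected(self):
        for mean, sd in [(0, 1), (-1, 1), (1, 0)]:
            with pytest.raises(ValueError):
                gamma_shape_rate(mean, sd)

    def test_sampled_moments_match(self, rng):
        """Gamma draws parameterized through (mean, sd) reproduce them."""
        mean, sd = 1.7, 0.9
        shape, rate = gamma_shape_rate(mean, sd)
        x = rng.gamma(shape, 1 / rate, 1_000_000)
        assert x.mean() == pytest.approx(mean, abs=4 * sd / 1000)
        assert x.std() == pytest.approx(sd, abs=0.01)


class TestWrappedCauchy:
    def test_rho_zero_is_circular_uniform(self):
        for theta in (-3.0, 0.0, 1.5, np.pi):
            assert wrapped_cauchy_logpdf(theta, 0.7, 0.0) == pytest.approx(
                -np.log(2 * np.pi)
            )

    def test_maximum_at_mean_direction(self):
        mu, rho = 0.4, 0.6
        expected = np.log((1 + rho) / ((1 - rho) * 2 * np.pi))
        assert wrapped_cauchy_logpdf(mu, mu, rho) == pytest.approx(expected)

    def test_integrates_to_one(self, rng):
        for _ in range(5):
            mu = rng.uniform(-np.pi, np.pi)
            rho = rng.uniform(0, 0.95)
            val, _ = quad(
                lambda th: np.exp(wrapped_cauchy_logpdf(th, mu, rho)), -np.pi, np.pi
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_reference(self, rng):
        for _ in range(10):
            mu = rng.uniform(-np.pi, np.pi)
            rho = rng.uniform(0.05, 0.95)
            theta = rng.uniform(-np.pi, np.pi)
            ref = stats.wrapcauchy.logpdf((theta - mu) % (2 * np.pi), rho)
            assert wrapped_cauchy_logpdf(theta, mu, rho) == pytest.approx(ref, rel=1e-10)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            wrapped_cauchy_logpdf(0.0, 0.0, 1.0)


class TestTransitionMatrix:
    def test_null_params_give_half(self, basis):
        p = random_params(np.random.default_rng(0))
        p.transitions.beta0[:] = 0.0
        p.transitions.b[:] = 0.0
        np.testing.assert_allclose(
            transition_matrix(100, p.transitions, basis), 0.5
        )

    def test_saturated_intercept_freezes_state(self, basis):
        p = random_params(np.random.default_rng(0))
        p.transitions.beta0[0] = -40.0
        p.transitions.b[0, :] = 0.0
        gam = transition_matrix(10, p.transitions, basis)
        np.testing.assert_allclose(gam[0], [1.0, 0.0], atol=1e-15)

    def test_matches_scalar_logit_computation(self, basis, rng):
        for _ in range(20):
            p = random_params(rng)
            day = int(rng.integers(1, 366))
            gam = transition_matrix(day, p.transitions, basis)
            g12 = expit(p.transitions.beta0[0] + basis.Z[day - 1] @ p.transitions.b[0])
            g21 = expit(p.transitions.beta0[1] + basis.Z[day - 1] @ p.transitions.b[1])
            np.testing.assert_allclose(gam, [[1 - g12, g12], [g21, 1 - g21]], rtol=1e-12)

    def test_rows_sum_to_one_all_days(self, basis, rng):
        for _ in range(20):
            p = random_params(rng)
            for day in range(1, 366, 30):
                assert transition_matrix(day, p.transitions, basis).sum(axis=1) == pytest.approx(
                    [1.0, 1.0], abs=1e-12
                )

    def test_day_out_of_range(self, basis):
        p = random_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            transition_matrix(0, p.transitions, basis)


class TestEmissionDensity:
    def test_both_missing_contribute_zero(self, rng):
        p = random_params(rng)
        assert emission_logdensity(np.nan, np.nan, 1, p.emissions) == 0.0

    def test_partial_missing_uses_present_term_only(self, rng):
        p = random_params(rng)
        e = p.emissions
        val = emission_logdensity(1.3, np.nan, 2, e)
        shape, rate = gamma_shape_rate(e.mu2_step, e.sd_step[1])
        assert val == pytest.approx(stats.gamma.logpdf(1.3, shape, scale=1 / rate))

    def test_matches_independent_densities(self, rng):
        for _ in range(20):
            p = random_params(rng)
            e = p.emissions
            step, turn = rng.gamma(2, 1), rng.uniform(-np.pi, np.pi)
            for state in (1, 2):
                i = state - 1
                shape, rate = gamma_shape_rate(e.step_means[i], e.sd_step[i])
                expected = stats.gamma.logpdf(step, shape, scale=1 / rate) + float(
                    wrapped_cauchy_logpdf(turn, e.mu_turn[i], e.rho_turn[i])
                )
                assert emission_logdensity(step, turn, state, e) == pytest.approx(expected)

    def test_nonpositive_step_rejected(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            emission_logdensity(0.0, 0.1, 1, p.emissions)

    def test_vectorized_logb_agrees_with_scalar(self, rng):
        p = random_params(rng)
        steps = np.array([0.5, np.nan, 2.0])
        turns = np.array([np.nan, 0.3, -1.0])
        lb = emission_logb(steps, turns, p.emissions)
        for t in range(3):
            for state in (1, 2):
                assert lb[t, state - 1] == pytest.approx(
                    emission_logdensity(steps[t], turns[t], state, p.emissions)
                )


class TestForwardLoglik:
    def test_single_fully_missing_day_gives_zero(self, basis, rng):
        s = DailyStepSeries("t", 2020, 50, [50], [np.nan], [np.nan])
        p = random_params(rng, start_days=(50,))
        assert forward_loglik(s, p, basis) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("T", [2, 4, 6, 8])
    def test_matches_exhaustive_enumeration(self, basis, T):
        rng = np.random.default_rng(100 + T)
        for _ in range(10):
            s = random_short_series(rng, T)
            p = random_params(rng, start_days=(s.start_day,))
            expected = enumerate_loglik(s, p, basis)
            assert forward_loglik(s, p, basis) == pytest.approx(expected, rel=1e-10)

    def test_label_permutation_symmetry(self, basis, rng):
        """Marginalizing over states is invariant to relabeling states
        together with all state-indexed parameters."""
        for _ in range(5):
            s = random_short_series(rng, 5)
            p = random_params(rng, start_days=(s.start_day,))
            swapped = enumerate_loglik(s, p, basis, swap_labels=True)
            assert forward_loglik(s, p, basis) == pytest.approx(swapped, rel=1e-10)

    def test_missing_day_enters_through_transitions_only(self, basis, rng):
        """Inserting a fully MISSING day between two observed days changes
        the likelihood exactly as the oracle with the extra transition."""
        start = 100
        step = np.array([np.nan, 1.2, np.nan, 0.8])
        turn = np.array([np.nan, np.nan, np.nan, 0.4])
        s = DailyStepSeries("t", 2020, start, np.arange(start, start + 4), step, turn)
        p = random_params(rng, start_days=(start,))
        assert forward_loglik(s, p, basis) == pytest.approx(
            enumerate_loglik(s, p, basis), rel=1e-10
        )


class TestViterbi:
    def brute_force_path(self, series, params, basis):
        T = len(series)
        phi = params.initial.get(series.start_day)
        best, best_lp = None, -np.inf
        # lexicographic order over paths makes ties resolve toward state 1
        for path in itertools.product((0, 1), repeat=T):
            lp = np.log(phi[path[0]]) + emission_logdensity(
                series.step_km[0], series.turn_rad[0], path[0] + 1, params.emissions
            )
            for t in range(1, T):
                gam = transition_matrix(int(series.day[t]), params.transitions, basis)
                lp += np.log(gam[path[t - 1], path[t]]) + emission_logdensity(
                    series.step_km[t], series.turn_rad[t], path[t] + 1, params.emissions
                )
            if lp > best_lp + 1e-12:
                best, best_lp = path, lp
        return np.array(best) + 1

    @pytest.mark.parametrize("T", [3, 5, 8])
    def test_matches_exhaustive_argmax(self, basis, T):
        rng = np.random.default_rng(200 + T)
        for _ in range(10):
            s = random_short_series(rng, T, p_missing=0.2)
            p = random_params(rng, start_days=(s.start_day,))
            np.testing.assert_array_equal(
                viterbi_decode(s, p, basis), self.brute_force_path(s, p, basis)
            )

    def test_uninformative_emissions_follow_transitions(self, basis, rng):
        """With no emission information (all observations missing) the
        decoded path is the most probable path of the Markov chain alone."""
        start = 120
        nanv = np.full(6, np.nan)
        s = DailyStepSeries("t", 2020, start, np.arange(start, start + 6), nanv, nanv)
        p = random_params(rng, start_days=(start,))
        np.testing.assert_array_equal(
            viterbi_decode(s, p, basis), self.brute_force_path(s, p, basis)
        )
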