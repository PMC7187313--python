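"""Scalar densities and the assembled joint posterior."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import lynxcast as lx
from lynxcast.dataset import MonitoringDataset
from lynxcast.model import (
    initial_state,
    log_obs_density,
    log_posterior,
    log_process_density,
)

PSI_MEAN = np.array([3.15, 2.48, 9.16]) / (3.15 + 2.48 + 9.16)


class TestProcessDensity:
    def test_zero_residual(self):
        n = np.array([5.0, 3.0, 20.0])
        val = log_process_density(n, n, 1.0)
        assert val == pytest.approx(3 * (-0.5 * math.log(2 * math.pi)), abs=1e-4)
        assert val == pytest.approx(-2.7568, abs=1e-4)

    def test_one_unit_log_residual(self):
        mu = np.array([5.0, 3.0, 20.0])
        n = mu * np.array([math.e, 1.0, 1.0])
        assert log_process_density(n, mu, 1.0) == pytest.approx(
            -2.7568 - 0.5, abs=1e-4
        )

    def test_normalizes_on_log_state_space(self):
        # single stage: density of log n integrates to 1
        mu, sigma = 12.0, 0.4
        total, _ = quad(
            lambda z: math.exp(
                log_process_density([math.exp(z)], [mu], sigma)
            ),
            math.log(mu) - 8 * sigma,
            math.log(mu) + 8 * sigma,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            log_process_density([0.0, 1.0, 1.0], [1.0, 1.0, 1.0], 0.3)


class TestObsDensity:
    def test_zero_count_unit_rate(self):
        assert log_obs_density(0, 0.5, 2.0) == pytest.approx(-1.0)

    def test_poisson_pmf_at_mode_exact_factorial(self):
        # independent oracle: exact log factorial by summation
        log_fact = sum(math.log(i) for i in range(1, 32))
        expected = 31 * math.log(31) - 31 - log_fact
        assert log_obs_density(31, 0.31, 100.0) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-2.6386, abs=1e-4)

    def test_simulated_mean_matches_rate(self, rng):
        draws = rng.poisson(0.31 * 100.0, size=100_000)
        assert draws.mean() == pytest.approx(31.0, abs=0.15)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            log_obs_density(3, 1.5, 10.0)


class TestInitialState:
    def test_hand_arithmetic(self):
        n = initial_state(10, 0.31, PSI_MEAN)
        assert n == pytest.approx([6.870, 5.409, 19.979], abs=0.01)

    def test_all_adult_composition(self):
        assert initial_state(8, 0.4, [0.0, 0.0, 1.0]) == pytest.approx([0, 0, 20])

    def test_total_conserved(self, rng):
        for _ in range(20):
            psi = rng.dirichlet([2, 2, 2])
            y1, f1 = rng.integers(1, 50), rng.uniform(0.1, 0.9)
            assert initial_state(y1, f1, psi).sum() == pytest.approx(y1 / f1)

    def test_zero_f_rejected(self):
        with pytest.raises(ValueError):
            initial_state(10, 0.0, PSI_MEAN)


def _toy_dataset():
    """One region in northern Sweden, two censuses."""
    return MonitoringDataset(
        regions=["R1"],
        region_to_area=np.array([1]),
        years=np.array([2000, 2001]),
        y=np.array([[10, 12]]),
        h=np.zeros((3, 1, 2)),
    )


class TestLogPosterior:
    theta = dict(
        phi1=0.9, phi2=0.95, r1=0.3, r2=0.4, rho=0.1,
        F=0.31, sigma_F=0.02, sigma_p=0.3,
        psi=np.array([0.2, 0.2, 0.6]),
    )

    def _latents(self, data):
        T = data.n_years
        f = np.full((3, T), 0.3)
        logn = np.zeros((3, 1, T))
        logn[:, 0, 1] = np.log([3.0, 2.0, 25.0])
        return {"f": f, "logn": logn}

    def test_term_by_term_oracle(self):
        """Totals agree with an independent scipy.stats decomposition."""
        data = _toy_dataset()
        priors = lx.default_prior_set()
        latents = self._latents(data)
        got = log_posterior(self.theta, latents, data, priors)

        th = self.theta
        expected = 0.0
        # parameter priors
        expected += stats.beta.logpdf(th["phi1"], 9.1, 1.01)
        expected += stats.beta.logpdf(th["phi2"], 20.5, 0.74)
        expected += stats.beta.logpdf(th["r1"], 4, 14)
        expected += stats.beta.logpdf(th["r2"], 55, 85)
        expected += stats.beta.logpdf(th["F"], 126, 278)
        expected += stats.beta.logpdf(th["sigma_F"], 20.7, 877)
        expected += stats.dirichlet.logpdf(
            th["psi"] / th["psi"].sum(), [3.15, 2.48, 9.16]
        )
        # detection-ratio hierarchy for both years
        spec = lx.beta_from_moments(th["F"], th["sigma_F"])
        expected += 2 * stats.beta.logpdf(0.3, spec.alpha, spec.beta)
        # initial state, process step, observations
        n1 = th["psi"] * (10 / 0.3)
        A = lx.build_projection_matrix(
            lx.VitalRates(th["phi1"], th["phi2"], th["r1"], th["r2"], th["rho"])
        )
        mu2 = A @ n1
        n2 = np.array([3.0, 2.0, 25.0])
        expected += stats.norm.logpdf(
            np.log(n2), np.log(mu2), th["sigma_p"]
        ).sum()
        expected += stats.poisson.logpmf(10, 0.3 * n1.sum())
        expected += stats.poisson.logpmf(12, 0.3 * n2.sum())

        assert got == pytest.approx(expected, abs=1e-8)

    def test_moving_count_away_from_rate_decreases_density(self):
        data = _toy_dataset()
        priors = lx.default_prior_set()
        latents = self._latents(data)
        base = log_posterior(self.theta, latents, data, priors)
        worse = MonitoringDataset(
            regions=["R1"],
            region_to_area=np.array([1]),
            years=np.array([2000, 2001]),
            y=np.array([[10, 40]]),  # rate at t=2 is 0.3 * 30 = 9
            h=np.zeros((3, 1, 2)),
        )
        assert log_posterior(self.theta, latents, worse, priors) < base

    def test_support_violation_returns_neg_inf(self):
        data = _toy_dataset()
        priors = lx.default_prior_set()
        latents = self._latents(data)
        bad = dict(self.theta, sigma_p=-0.1)
        assert log_posterior(bad, latents, data, priors) == -np.inf
        bad = dict(self.theta, rho=0.95)  # derived survival goes negative
        assert log_posterior(bad, latents, data, priors) == -np.inf
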