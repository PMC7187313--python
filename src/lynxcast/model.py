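"""Joint density of the lynx state-space model.

The model couples three layers:

* **Process** -- on the log scale, the latent stage vector follows the
  deterministic projection with lognormal noise:
  ``log n_t ~ Normal(log A(n_{t-1} - h_{t-1}), sigma_p^2 I)``; the process
  error is shared by all areas.
* **Observation** -- family-group counts are
  ``y_t ~ Poisson(f_{k,t} * sum_i n_{i,t})`` where the family-groups-per-
  female ratio ``f_{k,t}`` is a yearly beta random effect with area-level
  mean ``F_k`` and sd ``sigma_F_k``.
* **Initial conditions** -- the first census total ``y_1 / f_{k,1}`` is
  allocated to stages by a Dirichlet-distributed composition ``psi``.

This module exposes both scalar densities (used directly in tests and by
the spec-level API) and a vectorized :class:`LynxModel` /
:class:`ParameterState` pair consumed by the MCMC sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, xlogy

from .dataset import MonitoringDataset, N_STAGES
from .demography import STATE_FLOOR
from .priors import BetaSpec, PriorSet

__all__ = [
    "log_process_density",
    "log_obs_density",
    "initial_state",
    "log_posterior",
    "ParameterState",
    "LynxModel",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
_RATE_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# scalar densities


def log_process_density(n_t, mu_t, sigma_p: float) -> float:
    """Lognormal process log-density of one state vector.

    Sum over stages of ``Normal(log n | log mu, sigma_p)``; ``mu`` is the
    deterministic projection of the previous post-harvest state.
    """
    n_t = np.asarray(n_t, dtype=float)
    mu_t = np.asarray(mu_t, dtype=float)
    if np.any(n_t <= 0) or np.any(mu_t <= 0) or sigma_p <= 0:
        raise ValueError("states, projections and sigma_p must be positive")
    z = (np.log(n_t) - np.log(mu_t)) / sigma_p
    return float(np.sum(-0.5 * z * z - math.log(sigma_p) - 0.5 * _LOG_2PI))


def log_obs_density(y: int, f: float, n_total: float) -> float:
    """Poisson log-pmf of a family-group count at rate ``f * n_total``."""
    if y < 0 or int(y) != y:
        raise ValueError("y must be a nonnegative integer")
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    rate = f * n_total
    if rate <= 0.0:
        logger.warning("nonpositive observation rate; flooring at %g", _RATE_FLOOR)
        rate = _RATE_FLOOR
    return float(y * math.log(rate) - rate - gammaln(y + 1.0))


def initial_state(y1: float, f1: float, psi) -> np.ndarray:
    """First-census state: total females ``y1 / f1`` split by ``psi``."""
    if f1 <= 0.0 or f1 >= 1.0:
        raise ValueError("f1 must lie in (0, 1)")
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0) or not math.isclose(psi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("psi must lie on the 3-simplex")
    return psi * (float(y1) / f1)


# ---------------------------------------------------------------------------
# vectorized model


def _beta_logpdf(x, a, b):
    return xlogy(a - 1.0, x) + xlogy(b - 1.0, 1.0 - x) - betaln(a, b)


def _dirichlet_logpdf(x, conc):
    conc = np.asarray(conc, dtype=float)
    return float(
        np.sum(xlogy(conc - 1.0, x)) - np.sum(gammaln(conc)) + gammaln(conc.sum())
    )


@dataclass
class ParameterState:
    """One point in the sampler's state space (mutable numpy arrays).

    Per-area arrays always have 3 slots indexed by area code minus one;
    slots for areas absent from the data are carried but never updated.
    ``logn`` start-year columns are derived from ``psi`` and the
    first-year ``f`` (see :meth:`LynxModel.refresh_initial_states`).
    """

    phi1: float
    phi2: float
    r1: np.ndarray
    r2: np.ndarray
    rho: np.ndarray
    F: np.ndarray
    sigma_F: np.ndarray
    sigma_p: float
    psi: np.ndarray
    f: np.ndarray  # (3, T)
    logn: np.ndarray  # (3, J, T)

    def copy(self) -> "ParameterState":
        return ParameterState(
            phi1=self.phi1,
            phi2=self.phi2,
            r1=self.r1.copy(),
            r2=self.r2.copy(),
            rho=self.rho.copy(),
            F=self.F.copy(),
            sigma_F=self.sigma_F.copy(),
            sigma_p=self.sigma_p,
            psi=self.psi.copy(),
            f=self.f.copy(),
            logn=self.logn.copy(),
        )


class LynxModel:
    """Vectorized evaluation of the full posterior on a monitoring dataset."""

    def __init__(self, data: MonitoringDataset, priors: PriorSet):
        self.data = data
        self.priors = priors
        self.J = data.n_regions
        self.T = data.n_years
        self.area_idx = data.region_to_area - 1  # (J,) in 0..2
        self.active_areas = np.unique(self.area_idx)  # 0-based
        self.start = data.start_index
        self.obs_mask = data.obs_mask
        self.state_mask = data.state_mask
        # process terms exist for t > start (target year has a defined state)
        self.proc_mask = self.state_mask.copy()
        self.proc_mask[np.arange(self.J), self.start] = False
        self.f_mask = np.zeros((3, self.T), dtype=bool)
        am = data.area_year_mask()
        self.f_mask[: am.shape[0], :] = am
        # f sites feeding an initial condition need non-local updates
        self.init_f_sites = sorted(
            {(int(self.area_idx[j]), int(self.start[j])) for j in range(self.J)}
        )
        self.y = np.where(self.obs_mask, data.y, 0).astype(float)
        self._lgamma_y = gammaln(self.y + 1.0)
        self.h = data.h
        self._y0 = np.maximum(self.y[np.arange(self.J), self.start], 0.5)
        self._f_sites = np.nonzero(self.f_mask)  # (k_idx, t_idx) active pairs
        # stacked beta-prior shapes for the vectorized prior evaluation,
        # ordered to match _prior_values()
        ka = self.active_areas
        specs = (
            [priors.phi1, priors.phi2]
            + [priors.r1[k] for k in ka]
            + [priors.r2[k] for k in ka]
            + [priors.F[k] for k in ka]
            + [priors.sigma_F[k] for k in ka]
        )
        self._prior_a = np.array([s.alpha for s in specs])
        self._prior_b = np.array([s.beta for s in specs])

    def _prior_values(self, state: ParameterState) -> np.ndarray:
        ka = self.active_areas
        return np.concatenate(
            (
                [state.phi1, state.phi2],
                state.r1[ka],
                state.r2[ka],
                state.F[ka],
                state.sigma_F[ka],
            )
        )

    # -- pieces ----------------------------------------------------------

    def area_matrices(self, state: ParameterState) -> np.ndarray | None:
        """Projection matrices per area, ``(3, 3, 3)``; None if invalid.

        Matches :func:`..demography.build_projection_matrix` entry-wise
        (the unit test asserts this) but is evaluated vectorized across
        areas in the sampler's hot path.
        """
        phi1, phi2, rho = state.phi1, state.phi2, state.rho
        a21 = phi1 - rho * math.sqrt(phi1)
        a32 = phi2 - rho * math.sqrt(phi2)
        fec = phi2**0.25 - rho * phi2**0.125
        a12 = state.r1 * fec
        a13 = state.r2 * fec
        ka = self.active_areas
        if (
            a21[ka].min() < 0
            or a32[ka].min() < 0
            or a12[ka].min() < 0
            or a13[ka].min() < 0
        ):
            return None
        A = np.zeros((3, 3, 3))
        A[:, 0, 1] = a12
        A[:, 0, 2] = a13
        A[:, 1, 0] = a21
        A[:, 2, 1] = a32
        A[:, 2, 2] = a32
        return A

    def refresh_initial_states(self, state: ParameterState) -> None:
        """Recompute the derived start-year latent columns in place."""
        j = np.arange(self.J)
        f0 = state.f[self.area_idx, self.start]
        total = self._y0 / f0
        state.logn[:, j, self.start] = np.log(
            np.maximum(state.psi[:, None] * total[None, :], STATE_FLOOR)
        )

    def project_all(self, state: ParameterState, A: np.ndarray) -> np.ndarray:
        """Deterministic projections: ``mu[:, j, t+1]`` stored at index t.

        Returns ``(3, J, T)`` where slice ``t`` projects census ``t`` (after
        its harvest pulse) one year forward.
        """
        n = np.exp(state.logn)
        src = np.maximum(n - self.h, STATE_FLOOR)
        A_r = A[self.area_idx]  # (J, 3, 3)
        return np.einsum("jab,bjt->ajt", A_r, src)

    # -- support checks --------------------------------------------------

    def _support_ok(self, state: ParameterState) -> bool:
        pr = self.priors
        if not (0.0 < state.phi1 < 1.0 and 0.0 < state.phi2 < 1.0):
            return False
        if not pr.sigma_p.low < state.sigma_p < pr.sigma_p.high:
            return False
        ka = self.active_areas
        unit_vals = np.concatenate(
            (state.r1[ka], state.r2[ka], state.F[ka], state.sigma_F[ka])
        )
        if unit_vals.min() <= 0.0 or unit_vals.max() >= 1.0:
            return False
        rho_k = state.rho[ka]
        if rho_k.min() < pr.rho.low or rho_k.max() > pr.rho.high:
            return False
        if state.psi.min() <= 0.0 or abs(state.psi.sum() - 1.0) > 1e-8:
            return False
        f_active = state.f[self._f_sites]
        if f_active.min() <= 0.0 or f_active.max() >= 1.0:
            return False
        return True

    # -- full density ----------------------------------------------------

    def log_prior(self, state: ParameterState) -> float:
        # rho, sigma_p: uniform -> constant inside support (checked elsewhere)
        lp = float(
            np.sum(_beta_logpdf(self._prior_values(state), self._prior_a, self._prior_b))
        )
        lp += _dirichlet_logpdf(state.psi, self.priors.psi)
        return lp

    def f_hyper_shapes(self, state: ParameterState):
        """Beta shapes of the yearly detection-ratio random effect per area."""
        mean = state.F
        var = state.sigma_F * state.sigma_F
        bound = mean * (1.0 - mean)
        ka = self.active_areas
        if np.any(var[ka] >= bound[ka]):
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            c = bound / var - 1.0
        return mean * c, (1.0 - mean) * c

    def log_f_terms(self, state: ParameterState) -> float:
        shapes = self.f_hyper_shapes(state)
        if shapes is None:
            return -np.inf
        a, b = shapes
        k_idx, t_idx = self._f_sites
        return float(
            np.sum(_beta_logpdf(state.f[k_idx, t_idx], a[k_idx], b[k_idx]))
        )

    def log_process_terms(
        self, state: ParameterState, A: np.ndarray, src: np.ndarray | None = None
    ) -> float:
        if src is not None:
            A_r = A[self.area_idx]
            mu = np.einsum("jab,bjt->ajt", A_r, src)
        else:
            mu = self.project_all(state, A)  # projection from year t
        log_mu = np.log(np.maximum(mu, _RATE_FLOOR))
        # target year t+1 compared against projection stored at t
        resid = state.logn[:, :, 1:] - log_mu[:, :, :-1]
        mask = self.proc_mask[:, 1:]  # (J, T-1) target-year validity
        z = resid / state.sigma_p
        terms = -0.5 * z * z - math.log(state.sigma_p) - 0.5 * _LOG_2PI
        return float(np.sum(terms * mask[None, :, :]))

    def obs_rates(self, state: ParameterState) -> np.ndarray:
        ntot = np.exp(state.logn).sum(axis=0)  # (J, T)
        f_region = state.f[self.area_idx]  # (J, T)
        return np.maximum(f_region * ntot, _RATE_FLOOR)

    def log_obs_terms(self, state: ParameterState) -> float:
        rate = self.obs_rates(state)
        terms = self.y * np.log(rate) - rate - self._lgamma_y
        return float(np.sum(terms[self.obs_mask]))

    def log_posterior(self, state: ParameterState) -> float:
        """Unnormalized log posterior; ``-inf`` outside the support."""
        if not self._support_ok(state):
            return -np.inf
        A = self.area_matrices(state)
        if A is None:
            return -np.inf
        lp = self.log_prior(state)
        lp += self.log_f_terms(state)
        lp += self.log_process_terms(state, A)
        lp += self.log_obs_terms(state)
        return lp if np.isfinite(lp) else -np.inf

    # -- initialization --------------------------------------------------

    def initial_parameter_state(self, rng: np.random.Generator) -> ParameterState:
        """Overdispersed but support-respecting starting point."""
        pr = self.priors

        def beta_mean(spec: BetaSpec) -> float:
            return spec.alpha / (spec.alpha + spec.beta)

        jitter = lambda x, s: float(np.clip(x + rng.normal(0, s), 0.02, 0.98))
        state = ParameterState(
            phi1=jitter(beta_mean(pr.phi1), 0.03),
            phi2=jitter(beta_mean(pr.phi2), 0.01),
            r1=np.array([jitter(beta_mean(s), 0.03) for s in pr.r1]),
            r2=np.array([jitter(beta_mean(s), 0.03) for s in pr.r2]),
            rho=np.array([float(rng.uniform(0.02, 0.2)) for _ in range(3)]),
            F=np.array([jitter(beta_mean(s), 0.01) for s in pr.F]),
            sigma_F=np.array(
                [float(np.clip(beta_mean(s), 0.005, 0.2)) for s in pr.sigma_F]
            ),
            sigma_p=float(rng.uniform(0.15, 0.4)),
            psi=np.asarray(pr.psi, dtype=float) / np.sum(pr.psi),
            f=np.full((3, self.T), 0.3),
            logn=np.zeros((3, self.J, self.T)),
        )
        for k in self.active_areas:
            state.f[k] = np.clip(
                state.F[k] + rng.normal(0, state.sigma_F[k], self.T), 0.05, 0.95
            )
        # anchor latent totals to observed counts, carrying forward gaps
        sad = state.psi
        for j in range(self.J):
            k = self.area_idx[j]
            last_total = None
            for t in range(self.start[j], self.T):
                if self.obs_mask[j, t]:
                    last_total = max(self.y[j, t], 0.5) / state.f[k, t]
                total = last_total if last_total is not None else 1.0
                state.logn[:, j, t] = np.log(np.maximum(sad * total, STATE_FLOOR))
        self.refresh_initial_states(state)
        # clip rho down if the drawn vital rates would invalidate the matrix
        for k in self.active_areas:
            limit = min(math.sqrt(state.phi1), math.sqrt(state.phi2)) * 0.9
            state.rho[k] = min(state.rho[k], limit)
        return state


def log_posterior(
    theta: dict,
    latents: dict,
    data: MonitoringDataset,
    priors: PriorSet,
) -> float:
    """Functional wrapper over :meth:`LynxModel.log_posterior`.

    ``theta`` carries scalar/array parameters (``phi1``, ``phi2``, ``r1``,
    ``r2``, ``rho``, ``F``, ``sigma_F``, ``sigma_p``, ``psi``); ``latents``
    carries ``f`` of shape (3, T) and ``logn`` of shape (3, J, T).  Support
    violations return ``-inf`` rather than raising, so the function can sit
    directly inside a sampler.
    """
    model = LynxModel(data, priors)
    as_area = lambda x: np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    state = ParameterState(
        phi1=float(theta["phi1"]),
        phi2=float(theta["phi2"]),
        r1=as_area(theta["r1"]),
        r2=as_area(theta["r2"]),
        rho=as_area(theta["rho"]),
        F=as_area(theta["F"]),
        sigma_F=as_area(theta["sigma_F"]),
        sigma_p=float(theta["sigma_p"]),
        psi=np.asarray(theta["psi"], dtype=float),
        f=np.asarray(latents["f"], dtype=float).copy(),
        logn=np.asarray(latents["logn"], dtype=float).copy(),
    )
    model.refresh_initial_states(state)
    return model.log_posterior(state)
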