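"""Posterior sampling for the lynx state-space model.

The sampler is an adaptive Metropolis-within-Gibbs scheme over
``(theta, f, log n)``:

* demographic scalars (``phi1``, ``phi2``, per-area ``r1``, ``r2``,
  ``rho``, ``F``, ``sigma_F``, and ``sigma_p``) get sequential
  random-walk updates against the full joint density;
* the yearly detection ratios ``f`` are conditionally independent across
  area-years given the states, so they are updated in one vectorized
  parallel sweep (first-census years, which feed the initial conditions,
  are updated individually);
* the latent log-states form a Markov chain in time, so region-years of
  the same year-parity are conditionally independent and are updated in
  two vectorized "checkerboard" sweeps, proposing the three stages of a
  region-year jointly;
* the initial stage composition ``psi`` gets a Dirichlet random-walk
  block update with a Hastings correction.

Proposal scales adapt during burn-in (Robbins-Monro toward 44 percent
acceptance for scalars and 30 percent for the 3-dimensional blocks) and
are frozen afterwards, so the post-burn-in chain is a valid Markov chain.
Everything is driven by one ``numpy`` Generator per chain, seeded from
the run seed and the chain index: identical seed, settings, and data give
bit-identical chains.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .dataset import MonitoringDataset
from .demography import STATE_FLOOR, potential_growth_rate
from .model import LynxModel, ParameterState, _beta_logpdf, _dirichlet_logpdf
from .priors import PriorSet

__all__ = ["FitSettings", "PosteriorChains", "fit", "reduced_settings"]

_RATE_FLOOR = 1e-10


@dataclass(frozen=True)
class FitSettings:
    """MCMC run configuration.

    The defaults are the full-scale production settings (three chains of
    100,000 iterations after a 50,000 burn-in).  Tests and quick runs use
    :func:`reduced_settings`.
    """

    n_chains: int = 3
    n_iter: int = 100_000
    n_burnin: int = 50_000
    thin: int = 50
    seed: int = 0
    adapt_interval: int = 50
    store_latents: bool = True

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter <= self.n_burnin or self.thin < 1:
            raise ValueError("invalid MCMC settings")


def reduced_settings(
    seed: int = 0, n_chains: int = 3, n_iter: int = 6000, n_burnin: int = 3000,
    thin: int = 5,
) -> FitSettings:
    """Desk-scale settings for tests and experiments."""
    return FitSettings(
        n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin, thin=thin, seed=seed
    )


@dataclass
class PosteriorChains:
    """MCMC draws organized as chains x draws (x parameter dims).

    ``scalars`` maps names like ``"rho[1]"`` (area codes are 1-based) to
    ``(n_chains, n_draws)`` arrays and includes the derived growth rates
    ``"lambda[k]"``.  ``f`` has shape ``(C, D, 3, T)`` and ``logn`` shape
    ``(C, D, 3, J, T)`` when latents are stored.  ``meta`` records seed,
    settings, acceptance rates, and convergence flags.
    """

    scalars: dict[str, np.ndarray]
    f: np.ndarray | None
    logn: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.scalars.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.scalars.values())).shape[1]

    @property
    def scalar_names(self) -> list[str]:
        return list(self.scalars)

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one scalar, chains concatenated."""
        return self.scalars[name].reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 2.5%, median, 97.5%."""
        rows = []
        for name in self.scalar_names:
            draws = self.stacked(name)
            q = np.percentile(draws, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": draws.mean(),
                    "sd": draws.std(ddof=1),
                    "q2.5": q[0],
                    "median": q[1],
                    "q97.5": q[2],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name: str, level: float = 0.95):
        draws = self.stacked(name)
        lo = 100 * (1 - level) / 2
        return tuple(np.percentile(draws, [lo, 100 - lo]))

    def to_inference_data(self):
        """Export scalar draws as an ``arviz.InferenceData``."""
        import arviz as az

        return az.from_dict({k: v for k, v in self.scalars.items()})

    # -- persistence (one CSV per chain + JSON metadata) -----------------

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            frame = pd.DataFrame({k: v[c] for k, v in self.scalars.items()})
            frame.to_csv(out / f"chain_{c}.csv", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, in_dir) -> "PosteriorChains":
        from pathlib import Path

        path = Path(in_dir)
        frames = []
        c = 0
        while (path / f"chain_{c}.csv").exists():
            frames.append(pd.read_csv(path / f"chain_{c}.csv"))
            c += 1
        if not frames:
            raise FileNotFoundError(f"no chain CSVs under {path}")
        scalars = {
            name: np.stack([fr[name].to_numpy() for fr in frames])
            for name in frames[0].columns
        }
        meta = {}
        if (path / "metadata.json").exists():
            with open(path / "metadata.json") as fh:
                meta = json.load(fh)
        return cls(scalars=scalars, f=None, logn=None, meta=meta)


# ---------------------------------------------------------------------------
# sampler internals


class _Adaptive:
    """Robbins-Monro log-scale adaptation toward a target acceptance."""

    def __init__(self, shape, init_scale, target):
        self.log_scale = np.full(shape, math.log(init_scale))
        self.target = target
        self.accepts = np.zeros(shape)
        self.tries = np.zeros(shape)
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self):
        self.batch += 1
        rate = np.where(self.tries > 0, self.accepts / np.maximum(self.tries, 1), self.target)
        step = min(0.25, 2.0 / math.sqrt(self.batch))
        self.log_scale += step * (rate - self.target)
        self.log_scale = np.clip(self.log_scale, -12.0, 3.0)
        self.accepts[...] = 0.0
        self.tries[...] = 0.0


class _Scalar:
    """One scalar parameter's update recipe.

    ``kind`` selects the cheap partial likelihood that the scalar enters:
    ``"proc"`` (process terms, via the projection matrices) or
    ``"fhyper"`` (the detection-ratio hierarchy).  Unit-interval scalars
    additionally get an adaptive independence proposal: a beta
    distribution moment-matched (with inflated variance) to running
    burn-in estimates of the posterior, frozen when burn-in ends.  These
    global jumps mix parameters that single-site random walks cross only
    slowly because the latent states pin their full conditionals.
    """

    __slots__ = ("name", "get", "put", "kind", "prior_logpdf", "bounds",
                 "ind", "init_mean", "init_var")

    def __init__(self, name, get, put, kind, prior_logpdf, bounds,
                 ind=False, init_mean=0.5, init_var=1.0 / 12.0):
        self.name = name
        self.get = get
        self.put = put
        self.kind = kind
        self.prior_logpdf = prior_logpdf
        self.bounds = bounds
        self.ind = ind
        self.init_mean = init_mean
        self.init_var = init_var


def _matched_beta_shapes(mean: float, second_moment: float):
    """Beta shapes matched to (mean, 2x variance), clipped to feasibility."""
    var = second_moment - mean * mean
    mean = min(max(mean, 1e-3), 1.0 - 1e-3)
    var = float(np.clip(2.0 * var, 1e-6, 0.95 * mean * (1.0 - mean)))
    c = mean * (1.0 - mean) / var - 1.0
    return max(mean * c, 0.3), max((1.0 - mean) * c, 0.3)


def _scalar_params(model: LynxModel):
    from .priors import beta_moments

    pr = model.priors

    def beta_prior(spec):
        mean, sd = beta_moments(spec)
        lpdf = lambda x: float(_beta_logpdf(x, spec.alpha, spec.beta))
        return lpdf, mean, sd * sd

    params = []
    for name, spec in (("phi1", pr.phi1), ("phi2", pr.phi2)):
        lpdf, mean, var = beta_prior(spec)
        params.append(
            _Scalar(
                name,
                (lambda s, n=name: getattr(s, n)),
                (lambda s, x, n=name: setattr(s, n, x)),
                "proc",
                lpdf,
                (0.0, 1.0),
                ind=True,
                init_mean=mean,
                init_var=var,
            )
        )

    def arr_access(arr_name, k):
        get = lambda s, a=arr_name, k=k: getattr(s, a)[k]
        put = lambda s, x, a=arr_name, k=k: getattr(s, a).__setitem__(k, x)
        return get, put

    for arr_name, kind in (
        ("r1", "proc"), ("r2", "proc"), ("rho", "proc"),
        ("F", "fhyper"), ("sigma_F", "fhyper"),
    ):
        for k in model.active_areas:
            k = int(k)
            get, put = arr_access(arr_name, k)
            if arr_name == "rho":
                lpdf = lambda x: 0.0
                bounds = (pr.rho.low, pr.rho.high)
                mean, var = 0.1, 0.01
            else:
                spec = getattr(pr, arr_name)[k]
                lpdf, mean, var = beta_prior(spec)
                bounds = (0.0, 1.0)
            params.append(
                _Scalar(
                    f"{arr_name}[{k + 1}]", get, put, kind, lpdf, bounds,
                    ind=bounds == (0.0, 1.0), init_mean=mean, init_var=var,
                )
            )
    params.append(
        _Scalar(
            "sigma_p",
            lambda s: s.sigma_p,
            lambda s, x: setattr(s, "sigma_p", x),
            "proc",
            lambda x: 0.0,
            (pr.sigma_p.low, pr.sigma_p.high),
        )
    )
    return params


def _latent_sweep(model, state, A, adapt, parity, rng):
    """Parallel block update of same-parity region-year log-states."""
    T = model.T
    t_parity = (np.arange(T) % 2) == parity
    eligible = model.proc_mask & t_parity[None, :]
    if not eligible.any():
        return
    scale = adapt.scale
    eps = rng.normal(size=state.logn.shape) * scale[None, :, :]
    logn_new = np.where(eligible[None], state.logn + eps, state.logn)

    h = model.h
    src_old = np.maximum(np.exp(state.logn) - h, STATE_FLOOR)
    src_new = np.maximum(np.exp(logn_new) - h, STATE_FLOOR)
    A_r = A[model.area_idx]
    lmu_old = np.log(np.maximum(np.einsum("jab,bjt->ajt", A_r, src_old), _RATE_FLOOR))
    lmu_new = np.log(np.maximum(np.einsum("jab,bjt->ajt", A_r, src_new), _RATE_FLOOR))

    inv_two_var = 0.5 / (state.sigma_p * state.sigma_p)
    # process contribution at each target year t (projection stored at t-1)
    d_proc = np.zeros((model.J, T))
    diff_new = logn_new[:, :, 1:] - lmu_new[:, :, :-1]
    diff_old = state.logn[:, :, 1:] - lmu_old[:, :, :-1]
    contrib = -(diff_new**2 - diff_old**2).sum(axis=0) * inv_two_var
    d_proc[:, 1:] = np.where(model.proc_mask[:, 1:], contrib, 0.0)

    ntot_old = np.exp(state.logn).sum(axis=0)
    ntot_new = np.exp(logn_new).sum(axis=0)
    f_region = state.f[model.area_idx]
    rate_old = np.maximum(f_region * ntot_old, _RATE_FLOOR)
    rate_new = np.maximum(f_region * ntot_new, _RATE_FLOOR)
    d_obs = np.where(
        model.obs_mask,
        model.y * (np.log(rate_new) - np.log(rate_old)) - (rate_new - rate_old),
        0.0,
    )

    # per-site delta: own target term + the term it feeds one year ahead
    delta = d_proc + d_obs
    delta[:, :-1] += d_proc[:, 1:]

    accept = eligible & (np.log(rng.uniform(size=(model.J, T))) < delta)
    state.logn = np.where(accept[None], logn_new, state.logn)
    adapt.accepts += accept & eligible
    adapt.tries += eligible


def _f_sweep(model, state, adapt, rng, init_mask):
    """Parallel update of non-initial detection ratios f[k, t]."""
    eligible = model.f_mask & ~init_mask
    if not eligible.any():
        return
    prop = state.f + rng.normal(size=state.f.shape) * adapt.scale
    valid = eligible & (prop > 0.0) & (prop < 1.0)

    ntot = np.exp(state.logn).sum(axis=0)  # (J, T)
    y_sum = np.zeros((3, model.T))
    n_sum = np.zeros((3, model.T))
    for k in model.active_areas:
        rows = model.area_idx == k
        mask = model.obs_mask[rows]
        y_sum[k] = (model.y[rows] * mask).sum(axis=0)
        n_sum[k] = (ntot[rows] * mask).sum(axis=0)

    a, b = model.f_hyper_shapes(state)
    a_full = a[:, None]
    b_full = b[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = (
            y_sum * (np.log(np.where(valid, prop, 0.5)) - np.log(state.f))
            - (prop - state.f) * n_sum
            + _beta_logpdf(np.where(valid, prop, 0.5), a_full, b_full)
            - _beta_logpdf(state.f, a_full, b_full)
        )
    accept = valid & (np.log(rng.uniform(size=state.f.shape)) < delta)
    state.f = np.where(accept, prop, state.f)
    adapt.accepts += accept & eligible
    adapt.tries += eligible


def _scale_move(model, state, A, adapt, rng):
    """Joint rescaling of one area's states and detection ratios.

    Multiplies every latent state of the area by ``c = exp(eps)`` and
    divides its ``f`` values by ``c``: the observation rates ``f * N``
    are invariant, so the move travels along the abundance/detection
    ridge that single-site updates cross only slowly.  The acceptance
    ratio carries the Jacobian factor ``c**-(m+1)`` for the ``m`` rescaled
    ``f`` coordinates plus ``F_k``; the observation terms are exactly
    invariant and the process terms change only through the harvest
    offset, so the move explores the marginal uncertainty of abundance
    versus detection that single-site updates cross only slowly.
    """
    src = np.maximum(np.exp(state.logn) - model.h, STATE_FLOOR)
    proc_cur = model.log_process_terms(state, A, src)
    fh_cur = model.log_f_terms(state)
    prior_cur = model.log_prior(state)
    for idx, k in enumerate(model.active_areas):
        eps = float(rng.normal() * adapt.scale[idx])
        c = math.exp(eps)
        rows = model.area_idx == k
        mask_t = model.f_mask[k]
        f_new = state.f.copy()
        f_new[k, mask_t] = state.f[k, mask_t] / c
        F_new = state.F[k] / c
        adapt.tries[idx] += 1
        if (
            np.any(f_new[k, mask_t] >= 1.0)
            or np.any(f_new[k, mask_t] <= 0.0)
            or not 0.0 < F_new < 1.0
            or state.sigma_F[k] ** 2 >= F_new * (1.0 - F_new)
        ):
            continue
        logn_new = state.logn.copy()
        logn_new[:, rows, :] += eps
        old_f, old_logn, old_F = state.f, state.logn, state.F[k]
        state.f, state.logn = f_new, logn_new
        state.F[k] = F_new
        model.refresh_initial_states(state)
        src_new = np.maximum(np.exp(state.logn) - model.h, STATE_FLOOR)
        proc_new = model.log_process_terms(state, A, src_new)
        fh_new = model.log_f_terms(state)
        prior_new = model.log_prior(state)
        m = int(mask_t.sum())
        delta = (
            proc_new + fh_new + prior_new
            - proc_cur - fh_cur - prior_cur
            - (m + 1) * eps
        )
        if math.log(rng.uniform()) < delta:
            proc_cur, fh_cur, prior_cur = proc_new, fh_new, prior_new
            adapt.accepts[idx] += 1
        else:
            state.f, state.logn = old_f, old_logn
            state.F[k] = old_F
            model.refresh_initial_states(state)


def _process_residuals(model, state, A):
    """Standardized process residuals eps implied by the current state."""
    mu = model.project_all(state, A)
    log_mu = np.log(np.maximum(mu, _RATE_FLOOR))
    eps = np.zeros_like(state.logn)
    eps[:, :, 1:] = (state.logn[:, :, 1:] - log_mu[:, :, :-1]) / state.sigma_p
    return eps


def _rebuild_states(model, logn_start, eps, A, sigma_p):
    """Forward-reconstruct latent states from residuals and parameters.

    ``logn_start`` supplies the (possibly updated) first-census columns;
    subsequent years follow ``log n_t = log A(n_{t-1} - h_{t-1}) +
    sigma_p * eps_t``.
    """
    logn = logn_start.copy()
    A_r = A[model.area_idx]
    h = model.h
    for t in range(1, model.T):
        mask = model.proc_mask[:, t]
        if not mask.any():
            continue
        src = np.maximum(np.exp(logn[:, :, t - 1]) - h[:, :, t - 1], STATE_FLOOR)
        mu = np.einsum("jab,bj->aj", A_r, src)
        new_col = np.log(np.maximum(mu, _RATE_FLOOR)) + sigma_p * eps[:, :, t]
        logn[:, :, t] = np.where(mask[None, :], new_col, logn[:, :, t])
    return logn


def _ncp_moves(model, state, A, adapt, rng, eps):
    """Non-centered updates of phi1, phi2, and sigma_p.

    The full conditionals of these parameters given the latent states are
    far narrower than their marginals (the trajectory pins them), so
    centered random walks mix slowly.  Holding the standardized process
    residuals fixed and rebuilding the trajectory makes the acceptance
    ratio depend on the observation terms only, recovering marginal-rate
    mixing.  Returns the current projection matrices.
    """
    pr = model.priors
    obs_cur = model.log_obs_terms(state)
    specs = [
        ("phi1", (0.0, 1.0), pr.phi1),
        ("phi2", (0.0, 1.0), pr.phi2),
        ("sigma_p", (pr.sigma_p.low, pr.sigma_p.high), None),
    ]
    for idx, (name, bounds, prior_spec) in enumerate(specs):
        old = getattr(state, name)
        prop = old + float(rng.normal()) * adapt.scale[idx]
        adapt.tries[idx] += 1
        if not bounds[0] < prop < bounds[1]:
            continue
        setattr(state, name, prop)
        A_new = model.area_matrices(state) if name != "sigma_p" else A
        if A_new is None:
            setattr(state, name, old)
            continue
        old_logn = state.logn
        state.logn = _rebuild_states(model, state.logn, eps, A_new, state.sigma_p)
        obs_new = model.log_obs_terms(state)
        delta = obs_new - obs_cur
        if prior_spec is not None:
            delta += float(
                _beta_logpdf(prop, prior_spec.alpha, prior_spec.beta)
                - _beta_logpdf(old, prior_spec.alpha, prior_spec.beta)
            )
        if math.log(rng.uniform()) < delta:
            A, obs_cur = A_new, obs_new
            adapt.accepts[idx] += 1
        else:
            setattr(state, name, old)
            state.logn = old_logn
    return A


def _psi_ncp_move(model, state, A, conc, acc, rng, eps):
    """Non-centered Dirichlet random-walk update of psi.

    psi sets the first-census stage split; with residuals held fixed a
    psi change propagates through the whole trajectory, so acceptance is
    gated by the observation series rather than by the first process
    term only.
    """
    conc_fwd = conc * state.psi
    prop_psi = rng.dirichlet(conc_fwd)
    acc[1] += 1
    if np.any(prop_psi <= 1e-6):
        return
    prior_conc = np.asarray(model.priors.psi, dtype=float)
    old_psi, old_logn = state.psi.copy(), state.logn
    obs_cur = model.log_obs_terms(state)
    state.psi = prop_psi
    start = old_logn.copy()
    state.logn = start
    model.refresh_initial_states(state)  # rewrites first-census columns
    state.logn = _rebuild_states(model, state.logn, eps, A, state.sigma_p)
    delta = (
        model.log_obs_terms(state)
        - obs_cur
        + _dirichlet_logpdf(prop_psi, prior_conc)
        - _dirichlet_logpdf(old_psi, prior_conc)
        + _dirichlet_logpdf(old_psi, conc * prop_psi)
        - _dirichlet_logpdf(prop_psi, conc_fwd)
    )
    if math.log(rng.uniform()) < delta:
        acc[0] += 1
    else:
        state.psi = old_psi
        state.logn = old_logn


def _run_chain(model: LynxModel, settings: FitSettings, chain: int):
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=settings.seed, spawn_key=(chain,))
    )
    state = model.initial_parameter_state(rng)
    scalars = _scalar_params(model)
    s_adapt = _Adaptive(len(scalars), 0.05, 0.44)
    psi_conc = 200.0  # Dirichlet random-walk concentration (adapted)
    psi_acc = [0, 0]
    psi_ind_acc = [0, 0]
    psi_cind = 100.0  # independence-proposal concentration (adapted)
    psi_m = np.asarray(model.priors.psi, dtype=float) / np.sum(model.priors.psi)
    m1 = np.array([sc.init_mean for sc in scalars])
    m2 = m1**2 + np.array([sc.init_var for sc in scalars])
    ind_shapes = [_matched_beta_shapes(m1[i], m2[i]) for i in range(len(scalars))]
    latent_adapt = _Adaptive((model.J, model.T), 0.15, 0.30)
    f_adapt = _Adaptive((3, model.T), 0.02, 0.44)
    init_mask = np.zeros((3, model.T), dtype=bool)
    for k, t in model.init_f_sites:
        init_mask[k, t] = True
    initf_adapt = _Adaptive(len(model.init_f_sites), 0.02, 0.44)
    scale_adapt = _Adaptive(len(model.active_areas), 0.05, 0.44)
    ncp_adapt = _Adaptive(3, 0.05, 0.30)
    psi_ncp_conc = 100.0
    psi_ncp_acc = [0, 0]

    lp = model.log_posterior(state)
    if not np.isfinite(lp):
        raise RuntimeError("invalid initial state for MCMC")

    n_rec = settings.n_draws
    rec_scalars = {sc.name: np.empty(n_rec) for sc in scalars}
    for k in model.active_areas:
        rec_scalars[f"lambda[{k + 1}]"] = np.empty(n_rec)
    for i in range(3):
        rec_scalars[f"psi[{i + 1}]"] = np.empty(n_rec)
    rec_scalars["lp"] = np.empty(n_rec)
    rec_f = np.empty((n_rec, 3, model.T)) if settings.store_latents else None
    rec_logn = (
        np.empty((n_rec, 3, model.J, model.T)) if settings.store_latents else None
    )

    rec = 0
    for it in range(settings.n_iter):
        adapting = it < settings.n_burnin
        A = model.area_matrices(state)
        _latent_sweep(model, state, A, latent_adapt, it % 2, rng)
        _f_sweep(model, state, f_adapt, rng, init_mask)
        _scale_move(model, state, A, scale_adapt, rng)

        src = np.maximum(np.exp(state.logn) - model.h, STATE_FLOOR)
        proc_cur = model.log_process_terms(state, A, src)
        fhyper_cur = model.log_f_terms(state)
        obs_cur = model.log_obs_terms(state)

        # initial-year detection ratios (feed the derived first states)
        for idx, (k, t) in enumerate(model.init_f_sites):
            old = state.f[k, t]
            prop = old + rng.normal() * initf_adapt.scale[idx]
            initf_adapt.tries[idx] += 1
            if not 0.0 < prop < 1.0:
                continue  # out-of-support proposals count as rejected tries
            state.f[k, t] = prop
            model.refresh_initial_states(state)
            src_new = np.maximum(np.exp(state.logn) - model.h, STATE_FLOOR)
            proc_new = model.log_process_terms(state, A, src_new)
            obs_new = model.log_obs_terms(state)
            fh_new = model.log_f_terms(state)
            delta = (
                proc_new + obs_new + fh_new - proc_cur - obs_cur - fhyper_cur
            )
            if math.log(rng.uniform()) < delta:
                proc_cur, obs_cur, fhyper_cur = proc_new, obs_new, fh_new
                src = src_new
                initf_adapt.accepts[idx] += 1
            else:
                state.f[k, t] = old
                model.refresh_initial_states(state)

        # sequential scalar updates against cheap partial likelihoods
        for idx in rng.permutation(len(scalars)):
            sc = scalars[idx]
            old = sc.get(state)
            use_ind = sc.ind and rng.uniform() < 0.3
            if use_ind:
                aq, bq = ind_shapes[idx]
                prop = float(rng.beta(aq, bq))
            else:
                prop = old + rng.normal() * s_adapt.scale[idx]
                s_adapt.tries[idx] += 1
            if sc.bounds[0] < prop < sc.bounds[1]:
                sc.put(state, prop)
                if sc.kind == "proc":
                    A_new = model.area_matrices(state)
                    part_new = (
                        model.log_process_terms(state, A_new, src)
                        if A_new is not None
                        else -np.inf
                    )
                    part_cur = proc_cur
                else:
                    part_new = model.log_f_terms(state)
                    part_cur = fhyper_cur
                delta = (
                    part_new - part_cur
                    + sc.prior_logpdf(prop) - sc.prior_logpdf(old)
                )
                if use_ind:
                    delta += float(
                        _beta_logpdf(old, aq, bq) - _beta_logpdf(prop, aq, bq)
                    )
                if np.isfinite(part_new) and math.log(rng.uniform()) < delta:
                    if sc.kind == "proc":
                        proc_cur, A = part_new, A_new
                    else:
                        fhyper_cur = part_new
                    if not use_ind:
                        s_adapt.accepts[idx] += 1
                else:
                    sc.put(state, old)
            if adapting and sc.ind:
                x = sc.get(state)
                m1[idx] += 0.02 * (x - m1[idx])
                m2[idx] += 0.02 * (x * x - m2[idx])
                ind_shapes[idx] = _matched_beta_shapes(m1[idx], m2[idx])

        # block update of the initial stage composition psi: mixture of a
        # Dirichlet random walk and an adaptive independence proposal
        # centred on the running posterior mean
        prior_conc = np.asarray(model.priors.psi, dtype=float)
        use_ind = rng.uniform() < 0.5
        conc_fwd = psi_conc * state.psi
        conc_ind = psi_cind * psi_m
        prop_psi = rng.dirichlet(conc_ind if use_ind else conc_fwd)
        if use_ind:
            psi_ind_acc[1] += 1
        else:
            psi_acc[1] += 1
        if np.all(prop_psi > 1e-6):
            old_psi = state.psi.copy()
            state.psi = prop_psi
            model.refresh_initial_states(state)
            src_new = np.maximum(np.exp(state.logn) - model.h, STATE_FLOOR)
            proc_new = model.log_process_terms(state, A, src_new)
            delta = (
                proc_new
                - proc_cur
                + _dirichlet_logpdf(prop_psi, prior_conc)
                - _dirichlet_logpdf(old_psi, prior_conc)
            )
            if use_ind:
                delta += _dirichlet_logpdf(old_psi, conc_ind) - _dirichlet_logpdf(
                    prop_psi, conc_ind
                )
            else:
                delta += _dirichlet_logpdf(
                    old_psi, psi_conc * prop_psi
                ) - _dirichlet_logpdf(prop_psi, conc_fwd)
            if math.log(rng.uniform()) < delta:
                proc_cur = proc_new
                if use_ind:
                    psi_ind_acc[0] += 1
                else:
                    psi_acc[0] += 1
            else:
                state.psi = old_psi
                model.refresh_initial_states(state)
        if adapting:
            psi_m = psi_m + 0.02 * (state.psi - psi_m)
            psi_m /= psi_m.sum()

        # non-centered moves for the trajectory-pinned parameters
        # (residual-preserving, so the eps computed once stays valid)
        eps_resid = _process_residuals(model, state, A)
        A = _ncp_moves(model, state, A, ncp_adapt, rng, eps_resid)
        _psi_ncp_move(model, state, A, psi_ncp_conc, psi_ncp_acc, rng, eps_resid)

        if adapting and (it + 1) % settings.adapt_interval == 0:
            s_adapt.update()
            latent_adapt.update()
            f_adapt.update()
            initf_adapt.update()
            scale_adapt.update()
            step = min(0.25, 2.0 / math.sqrt(s_adapt.batch))
            rate = psi_acc[0] / max(psi_acc[1], 1)
            psi_conc *= math.exp(step * (0.30 - rate))
            psi_conc = float(np.clip(psi_conc, 5.0, 1e6))
            psi_acc = [0, 0]
            rate_ind = psi_ind_acc[0] / max(psi_ind_acc[1], 1)
            psi_cind *= math.exp(step * (0.30 - rate_ind))
            psi_cind = float(np.clip(psi_cind, 5.0, 1e5))
            psi_ind_acc = [0, 0]
            ncp_adapt.update()
            rate_ncp = psi_ncp_acc[0] / max(psi_ncp_acc[1], 1)
            psi_ncp_conc *= math.exp(step * (0.30 - rate_ncp))
            psi_ncp_conc = float(np.clip(psi_ncp_conc, 5.0, 1e6))
            psi_ncp_acc = [0, 0]

        if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
            for sc in scalars:
                rec_scalars[sc.name][rec] = sc.get(state)
            A_rec = model.area_matrices(state)
            for k in model.active_areas:
                rec_scalars[f"lambda[{k + 1}]"][rec] = potential_growth_rate(A_rec[k])
            for i in range(3):
                rec_scalars[f"psi[{i + 1}]"][rec] = state.psi[i]
            rec_scalars["lp"][rec] = model.log_posterior(state)
            if settings.store_latents:
                rec_f[rec] = state.f
                rec_logn[rec] = state.logn
            rec += 1

    assert rec == n_rec
    accept_rates = {
        "scalars": {
            scalars[i].name: float(np.exp(s_adapt.log_scale[i]))
            for i in range(len(scalars))
        },
    }
    return rec_scalars, rec_f, rec_logn, accept_rates


def fit(
    data: MonitoringDataset,
    priors: PriorSet | None = None,
    settings: FitSettings | None = None,
) -> PosteriorChains:
    """Fit the state-space model by adaptive Metropolis-within-Gibbs MCMC.

    Returns posterior chains whose stationary distribution is the joint
    posterior of demographic parameters, detection ratios, and latent
    states.  Convergence (Brooks-Gelman upper limits below 1.11 on every
    scalar) is checked when at least two chains were run and flagged in
    ``meta["converged"]``; non-convergence is not fatal.
    """
    priors = priors if priors is not None else _default_priors()
    settings = settings if settings is not None else FitSettings()
    model = LynxModel(data, priors)

    per_chain = [
        _run_chain(model, settings, chain) for chain in range(settings.n_chains)
    ]
    names = per_chain[0][0].keys()
    scalars = {
        name: np.stack([chain[0][name] for chain in per_chain]) for name in names
    }
    f_draws = (
        np.stack([chain[1] for chain in per_chain])
        if settings.store_latents
        else None
    )
    logn_draws = (
        np.stack([chain[2] for chain in per_chain])
        if settings.store_latents
        else None
    )
    meta = {
        "seed": settings.seed,
        "settings": asdict(settings),
        "n_regions": data.n_regions,
        "n_years": data.n_years,
        "regions": list(data.regions),
        "region_to_area": data.region_to_area.tolist(),
        "years": data.years.tolist(),
        "proposal_scales": per_chain[0][3],
    }
    chains = PosteriorChains(scalars=scalars, f=f_draws, logn=logn_draws, meta=meta)
    if settings.n_chains >= 2:
        from .diagnostics import gelman_rubin

        diag = gelman_rubin(chains)
        worst = float(diag["upper"].max())
        meta["max_psrf_upper"] = worst
        meta["converged"] = bool(worst < 1.11)
    return chains


def _default_priors() -> PriorSet:
    from .priors import default_prior_set

    return default_prior_set()
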