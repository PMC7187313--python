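"""Quota decision models: strict proportional vs. threshold harvest.

Managers' past quota setting is regressed on the previous census:
``q_t ~ Poisson(H_t)`` with ``log H_t ~ Normal(log(max(eps, b0 + b1 *
x_{t-1})), sigma_q^2)``.  Model 1 (strict proportional strategy) omits
the intercept; model 2 (threshold strategy with increasing proportion)
includes it, and a negative intercept implies a census threshold
``-b0 / b1`` below which the predicted quota collapses to zero.

The published mean form wraps ``max(0, .)`` around a log whose argument
can be nonpositive; here the floor is applied to the *argument*
(``log(max(eps, b0 + b1 x))`` with ``eps = 1e-6``), which keeps the
density proper while preserving the intended zero-quota regime below
the threshold.

The latent ``H_t`` are handled by data augmentation (one latent per
pair); the marginal likelihood helper integrates them out by
Gauss-Hermite quadrature and serves as the independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .inference import FitSettings, _Adaptive
from .priors import PriorSet, default_prior_set

__all__ = [
    "QuotaSeries",
    "QuotaPosterior",
    "quota_log_likelihood",
    "fit_quota_model",
    "threshold_summary",
    "compare_slopes",
    "EPS_FLOOR",
]

EPS_FLOOR = 1e-6


@dataclass(frozen=True)
class QuotaSeries:
    """Paired series (census count in year t-1, quota set in year t)."""

    x: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=int))
        object.__setattr__(self, "q", np.asarray(self.q, dtype=int))
        if self.x.shape != self.q.shape or self.x.ndim != 1:
            raise ValueError("x and q must be equal-length 1-D arrays")
        if np.any(self.x < 0) or np.any(self.q < 0):
            raise ValueError("census counts and quotas must be nonnegative")

    def __len__(self) -> int:
        return len(self.x)


def _mean_location(b0: float, b1: float, x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(b0 + b1 * x, EPS_FLOOR))


def quota_log_likelihood(
    b0: float, b1: float, sigma_q: float, series: QuotaSeries, *, n_nodes: int = 60
) -> float:
    """Marginal log-likelihood with the latent quota means integrated out.

    Gauss-Hermite quadrature over ``log H``; in the ``sigma_q -> 0``
    limit this reduces to the plain Poisson likelihood at the regression
    mean.  Invariant to the ordering of the pairs.
    """
    if sigma_q < 0:
        return -np.inf
    x = np.asarray(series.x, dtype=float)
    q = np.asarray(series.q, dtype=float)
    m = _mean_location(b0, b1, x)
    if sigma_q < 1e-8:
        rate = np.exp(m)
        return float(np.sum(q * m - rate - gammaln(q + 1.0)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # log H = m + sigma_q * z, z ~ N(0, 1)
    logH = m[:, None] + sigma_q * nodes[None, :]
    log_pois = q[:, None] * logH - np.exp(logH) - gammaln(q + 1.0)[:, None]
    log_w = np.log(weights / math.sqrt(2.0 * math.pi))[None, :]
    per_pair = np.logaddexp.reduce(log_pois + log_w, axis=1)
    return float(np.sum(per_pair))


@dataclass
class QuotaPosterior:
    """Posterior draws of the quota regression (chains x draws)."""

    model: str  # "proportional" or "threshold"
    b1: np.ndarray
    sigma_q: np.ndarray
    b0: np.ndarray | None = None
    logH: np.ndarray | None = None
    meta: dict | None = None

    @property
    def threshold_draws(self) -> np.ndarray:
        """Per-draw census threshold ``-b0 / b1`` (model 2 only)."""
        if self.model != "threshold":
            raise ValueError("threshold is defined only for the threshold model")
        return (-self.b0 / self.b1).reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = {}
        if self.b0 is not None:
            rows["b0"] = self.b0.reshape(-1)
        rows["b1"] = self.b1.reshape(-1)
        rows["sigma_q"] = self.sigma_q.reshape(-1)
        if self.model == "threshold":
            rows["threshold"] = self.threshold_draws
        out = []
        for name, draws in rows.items():
            q = np.percentile(draws, [2.5, 50.0, 97.5])
            out.append(
                {
                    "parameter": name,
                    "mean": draws.mean(),
                    "sd": draws.std(ddof=1),
                    "q2.5": q[0],
                    "median": q[1],
                    "q97.5": q[2],
                }
            )
        return pd.DataFrame(out).set_index("parameter")


def fit_quota_model(
    series: QuotaSeries,
    model: str = "threshold",
    priors: PriorSet | None = None,
    settings: FitSettings | None = None,
) -> QuotaPosterior:
    """Fit the quota regression by data-augmented Metropolis-within-Gibbs.

    Latent ``log H_t`` get vectorized parallel updates (they are
    conditionally independent given the regression); the coefficients
    and ``sigma_q`` get adaptive random-walk updates against the
    augmented density.
    """
    if model not in ("proportional", "threshold"):
        raise ValueError("model must be 'proportional' or 'threshold'")
    if len(series) < 3:
        raise ValueError("need at least 3 (census, quota) pairs")
    priors = priors if priors is not None else default_prior_set()
    settings = settings if settings is not None else FitSettings(
        n_chains=3, n_iter=12_000, n_burnin=4_000, thin=4
    )
    x = np.asarray(series.x, dtype=float)
    q = np.asarray(series.q, dtype=float)
    n = len(series)
    b_sd = priors.b.sd
    sq_lo, sq_hi = priors.sigma_q.low, priors.sigma_q.high
    use_b0 = model == "threshold"

    def log_aug(b0, b1, sq, logH):
        if not sq_lo < sq < sq_hi:
            return -np.inf
        m = _mean_location(b0, b1, x)
        ll = np.sum(q * logH - np.exp(logH))  # gammaln(q+1) constant
        z = (logH - m) / sq
        ll += np.sum(-0.5 * z * z) - n * math.log(sq)
        lp = -0.5 * (b1 / b_sd) ** 2
        if use_b0:
            lp += -0.5 * (b0 / b_sd) ** 2
        return float(ll + lp)

    chains_b0, chains_b1, chains_sq, chains_lh = [], [], [], []
    for chain in range(settings.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=settings.seed, spawn_key=(chain, 7))
        )
        # least-squares start on the positive-quota pairs, which is where
        # the regression line is identified
        pos = q > 0
        if use_b0 and pos.sum() >= 2 and np.ptp(x[pos]) > 0:
            b1_ls = float(np.cov(x[pos], q[pos], ddof=0)[0, 1] / x[pos].var())
            b0_ls = float(q[pos].mean() - b1_ls * x[pos].mean())
        else:
            b1_ls = float(q.sum() / max(x.sum(), 1.0))
            b0_ls = 0.0
        b1_0 = max(b1_ls, 0.02) * rng.uniform(0.8, 1.2)
        b0_0 = b0_ls + rng.normal() * (abs(b0_ls) * 0.1 + 1.0) if use_b0 else 0.0
        sq_0 = rng.uniform(0.1, 0.6)
        x_pivot = float(x[pos].mean()) if pos.any() else float(max(x.mean(), 1.0))
        # start latents at the observed quotas where positive and at the
        # regression location for zero-quota pairs (below the threshold
        # the location is log(eps), far from log 0.5)
        m0 = _mean_location(b0_0, b1_0, x)
        logH = np.where(q > 0, np.log(np.maximum(q, 0.5)), m0)
        scal = _Adaptive(3, 0.1, 0.44)
        scal.log_scale[:2] = math.log(
            max(0.5, 0.05 * (abs(b0_0) + 1.0))
        )  # coefficient scales
        lat = _Adaptive(n, 0.3, 0.44)
        rot = _Adaptive(1, 2.0, 0.3)
        cur = log_aug(b0_0, b1_0, sq_0, logH)
        params = [b0_0, b1_0, sq_0]
        n_rec = settings.n_draws
        rec = {k: np.empty(n_rec) for k in ("b0", "b1", "sigma_q")}
        rec_lh = np.empty((n_rec, n))
        r = 0
        for it in range(settings.n_iter):
            # latent sweep (conditionally independent)
            prop = logH + rng.normal(size=n) * lat.scale
            m = _mean_location(params[0], params[1], x)
            d = (
                q * (prop - logH)
                - (np.exp(prop) - np.exp(logH))
                - 0.5 * ((prop - m) ** 2 - (logH - m) ** 2) / params[2] ** 2
            )
            acc = np.log(rng.uniform(size=n)) < d
            logH = np.where(acc, prop, logH)
            lat.accepts += acc
            lat.tries += 1
            cur = log_aug(params[0], params[1], params[2], logH)
            # coefficient updates
            idx_list = ([0, 1, 2] if use_b0 else [1, 2])
            for idx in idx_list:
                old = params[idx]
                params[idx] = old + rng.normal() * scal.scale[idx]
                new = log_aug(params[0], params[1], params[2], logH)
                scal.tries[idx] += 1
                if math.log(rng.uniform()) < new - cur:
                    cur = new
                    scal.accepts[idx] += 1
                else:
                    params[idx] = old
            if use_b0:
                # correlated move along the intercept/slope ridge: shift the
                # intercept while holding the prediction at the mean census
                # fixed (symmetric proposal, so no Hastings term)
                shift = rng.normal() * rot.scale[0]
                old0, old1 = params[0], params[1]
                params[0] = old0 + shift
                params[1] = old1 - shift / x_pivot
                new = log_aug(params[0], params[1], params[2], logH)
                rot.tries[0] += 1
                if math.log(rng.uniform()) < new - cur:
                    cur = new
                    rot.accepts[0] += 1
                else:
                    params[0], params[1] = old0, old1
            if it < settings.n_burnin and (it + 1) % settings.adapt_interval == 0:
                scal.update()
                lat.update()
                rot.update()
            if it >= settings.n_burnin and (
                it - settings.n_burnin
            ) % settings.thin == 0:
                rec["b0"][r], rec["b1"][r], rec["sigma_q"][r] = params
                rec_lh[r] = logH
                r += 1
        chains_b0.append(rec["b0"])
        chains_b1.append(rec["b1"])
        chains_sq.append(rec["sigma_q"])
        chains_lh.append(rec_lh)

    post = QuotaPosterior(
        model=model,
        b1=np.stack(chains_b1),
        sigma_q=np.stack(chains_sq),
        b0=np.stack(chains_b0) if use_b0 else None,
        logH=np.stack(chains_lh),
        meta={"seed": settings.seed, "n_pairs": n, "model": model},
    )
    return post


def threshold_summary(posterior: QuotaPosterior) -> dict:
    """Mean, sd, 95% interval and P(<= 0) of the census threshold -b0/b1.

    Draws with ``b0 >= 0`` yield nonpositive thresholds and count toward
    ``P(threshold <= 0)`` -- evidence against a real threshold.
    """
    draws = posterior.threshold_draws
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "p_leq_0": float(np.mean(draws <= 0.0)),
    }


def compare_slopes(a: QuotaPosterior, b: QuotaPosterior, seed: int = 0) -> float:
    """P(slope_a > slope_b) by pairing independent posterior draws."""
    rng = np.random.default_rng(seed)
    da = a.b1.reshape(-1)
    db = b.b1.reshape(-1)
    size = max(len(da), len(db))
    return float(
        np.mean(rng.choice(da, size=size) > rng.choice(db, size=size))
    )
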