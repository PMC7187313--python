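"""Convergence and model-checking tools: Brooks-Gelman diagnostics,
posterior predictive checks, residual autocorrelation, and the
prior/initial-condition sensitivity procedure."""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .dataset import MonitoringDataset
from .priors import PriorSet

if TYPE_CHECKING:  # pragma: no cover
    from .inference import FitSettings, PosteriorChains

__all__ = [
    "gelman_rubin",
    "posterior_predictive_check",
    "residual_acf",
    "run_sensitivity",
    "freeman_tukey",
]


def _psrf(draws: np.ndarray) -> tuple[float, float]:
    """Brooks-Gelman potential scale reduction factor (point, upper 97.5%).

    ``draws`` has shape (chains, iterations).  Follows the corrected
    estimator with the sampling-variability degrees-of-freedom adjustment
    and an F-quantile upper limit, i.e. the form standard MCMC toolboxes
    report.
    """
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return (1.0, 1.0) if B <= 0 else (np.inf, np.inf)
    muhat = draws.mean()
    var_w = chain_vars.var(ddof=1) / m
    var_b = (2.0 * B**2) / (m - 1)
    cov_wb = (n / m) * (
        np.cov(chain_vars, chain_means**2, ddof=1)[0, 1]
        - 2.0 * muhat * np.cov(chain_vars, chain_means, ddof=1)[0, 1]
    )
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
    var_V = (
        ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
         + 2 * (n - 1) * (1 + 1 / m) * cov_wb)
        / n**2
    )
    df_V = 2.0 * V**2 / var_V if var_V > 0 else np.inf
    df_adj = (df_V + 3.0) / (df_V + 1.0) if np.isfinite(df_V) else 1.0
    w_df = 2.0 * W**2 / (var_w * m) if var_w > 0 else 1e9
    r2_fixed = (n - 1) / n
    r2_random = (1.0 + 1.0 / m) * (B / n) / W
    point = np.sqrt(df_adj * (r2_fixed + r2_random))
    upper = np.sqrt(
        df_adj * (r2_fixed + f_dist.ppf(0.975, m - 1, w_df) * r2_random)
    )
    return float(point), float(upper)


def gelman_rubin(chains: "PosteriorChains", names=None) -> pd.DataFrame:
    """Per-parameter scale reduction factors with upper confidence limits.

    Requires at least two chains.  The conventional pass criterion is an
    upper limit below 1.1 (1.11 is used as the default threshold in this
    package's convergence flag).
    """
    if chains.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostics require at least 2 chains")
    names = list(names) if names is not None else [
        n for n in chains.scalar_names if n != "lp"
    ]
    rows = []
    for name in names:
        draws = chains.scalars[name]
        if np.allclose(draws, draws.flat[0]):
            point, upper = 1.0, 1.0  # constant parameter (e.g. fixed prior)
        else:
            point, upper = _psrf(draws)
        rows.append({"parameter": name, "psrf": point, "upper": upper})
    return pd.DataFrame(rows).set_index("parameter")


def freeman_tukey(y: np.ndarray, rate: np.ndarray) -> float:
    """Freeman-Tukey discrepancy ``sum (sqrt(y) - sqrt(rate))**2``."""
    return float(np.sum((np.sqrt(y) - np.sqrt(rate)) ** 2))


def posterior_predictive_check(
    chains: "PosteriorChains",
    data: MonitoringDataset,
    *,
    statistic=freeman_tukey,
    seed: int = 0,
) -> pd.DataFrame:
    """Bayesian P values per management region.

    For each retained draw, replicate counts are simulated from the
    observation model at that draw's rates ``f_{k,t} * sum_i n``; the P
    value is the fraction of draws whose replicate discrepancy is at least
    the observed one.  Values near 0 or 1 indicate lack of fit.  The
    default discrepancy is Freeman-Tukey; pass any ``statistic(y, rate)``.
    """
    if chains.logn is None or chains.f is None:
        raise ValueError("posterior predictive checks need stored latent draws")
    rng = np.random.default_rng(seed)
    C, D = chains.n_chains, chains.n_draws
    area_idx = data.region_to_area - 1
    rows = []
    ntot = np.exp(chains.logn).sum(axis=2)  # (C, D, J, T)
    f_region = chains.f[:, :, area_idx, :]  # (C, D, J, T)
    rates = f_region * ntot
    total_obs = np.zeros(C * D)
    total_rep = np.zeros(C * D)
    for j, label in enumerate(data.regions):
        mask = data.obs_mask[j]
        y_obs = data.y[j, mask]
        rate_j = rates[:, :, j, mask].reshape(C * D, -1)
        y_rep = rng.poisson(rate_j)
        if statistic is freeman_tukey:
            t_obs = np.sum((np.sqrt(y_obs)[None, :] - np.sqrt(rate_j)) ** 2, axis=1)
            t_rep = np.sum((np.sqrt(y_rep) - np.sqrt(rate_j)) ** 2, axis=1)
        else:
            t_obs = np.array([statistic(y_obs, r) for r in rate_j])
            t_rep = np.array([statistic(yr, r) for yr, r in zip(y_rep, rate_j)])
        total_obs += t_obs
        total_rep += t_rep
        rows.append({"region": label, "p_value": float(np.mean(t_rep >= t_obs))})
    # dataset-level discrepancy: the per-draw sum over regions
    rows.append(
        {"region": "_total", "p_value": float(np.mean(total_rep >= total_obs))}
    )
    return pd.DataFrame(rows).set_index("region")


def residual_acf(
    chains: "PosteriorChains", data: MonitoringDataset, max_lag: int = 10
) -> pd.DataFrame:
    """Autocorrelation of observation residuals per region.

    Residuals are ``y - posterior mean of (f * sum n)``; the lag-0 value
    is exactly 1.  Series shorter than ``max_lag`` are truncated.
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    if chains.logn is None or chains.f is None:
        raise ValueError("residual ACF needs stored latent draws")
    area_idx = data.region_to_area - 1
    ntot = np.exp(chains.logn).sum(axis=2)
    f_region = chains.f[:, :, area_idx, :]
    mean_rate = (f_region * ntot).mean(axis=(0, 1))  # (J, T)
    rows = []
    for j, label in enumerate(data.regions):
        mask = data.obs_mask[j]
        resid = data.y[j, mask] - mean_rate[j, mask]
        lags = min(max_lag, len(resid) - 1)
        values = sm_acf(resid, nlags=lags, fft=False)
        for lag, value in enumerate(values):
            rows.append({"region": label, "lag": lag, "acf": float(value)})
    return pd.DataFrame(rows)


def run_sensitivity(
    data: MonitoringDataset,
    priors: PriorSet,
    settings: "FitSettings",
    *,
    relax=None,
    sigma_F_factor: float = 1.3,
    census_perturbations=(0.7, 1.3),
) -> pd.DataFrame:
    """Refit under prior and initial-condition perturbations.

    ``relax`` lists ``(name, area)`` pairs whose informative beta prior is
    swapped for uniform(0, 1), one at a time; additionally the sigma_F
    prior mean is inflated by ``sigma_F_factor`` and the first-year census
    counts are scaled by each factor in ``census_perturbations``.  Reports
    the posterior mean and sd of the growth rate per area for every
    variant next to the baseline.
    """
    from .inference import fit

    if relax is None:
        relax = [("phi1", None), ("phi2", None)] + [
            (name, int(area))
            for name in ("r1", "r2")
            for area in np.unique(data.region_to_area)
        ]

    variants: list[tuple[str, MonitoringDataset, PriorSet]] = [
        ("baseline", data, priors)
    ]
    for name, area in relax:
        tag = f"vague {name}" + (f" area {area}" if area else "")
        variants.append((tag, data, priors.relax(name, area)))
    variants.append(
        (f"sigma_F x{sigma_F_factor}", data, priors.inflate_sigma_F(sigma_F_factor))
    )
    for factor in census_perturbations:
        perturbed = _perturb_initial_census(data, factor)
        variants.append((f"initial census x{factor}", perturbed, priors))

    rows = []
    for tag, d, p in variants:
        chains = fit(d, p, settings)
        for k in np.unique(d.region_to_area):
            draws = chains.stacked(f"lambda[{k}]")
            rows.append(
                {
                    "variant": tag,
                    "area": int(k),
                    "lambda_mean": float(draws.mean()),
                    "lambda_sd": float(draws.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def _perturb_initial_census(data: MonitoringDataset, factor: float) -> MonitoringDataset:
    y = data.y.copy()
    for j, s in enumerate(data.start_index):
        y[j, s] = max(int(round(y[j, s] * factor)), 1)
    return MonitoringDataset(
        regions=list(data.regions),
        region_to_area=data.region_to_area.copy(),
        years=data.years.copy(),
        y=y,
        h=data.h.copy(),
        h_male=None if data.h_male is None else data.h_male.copy(),
        quota=None if data.quota is None else data.quota.copy(),
        goals=dict(data.goals),
    )
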