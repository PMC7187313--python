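"""Predictive-process forecasting of family groups under harvest scenarios.

Forecasts propagate every retained posterior draw (parameters *and*
final-year latent states) through the process model: subtract the harvest
pulse, project with that draw's matrices, add lognormal process noise,
and convert females to observable family groups with a freshly drawn
yearly detection ratio and Poisson sampling.  Probabilities of ending
below / within / above a management objective are empirical proportions
of the draws -- the full uncertainty (parameter, process, observation)
is carried into every number.

Timing follows the management cycle: the step from the last data census
uses the recorded harvest that already followed it, while scenario quotas
apply to later (forecasted) censuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MonitoringDataset
from .demography import STATE_FLOOR
from .priors import beta_from_moments
from .simulate import DEFAULT_COMPOSITION

__all__ = [
    "HarvestScenario",
    "ForecastTable",
    "allocate_harvest",
    "forecast",
    "goal_probabilities",
]

_RATE_FLOOR = 1e-10


@dataclass(frozen=True)
class HarvestScenario:
    """A per-region quota with the sex/age allocation convention.

    ``quota`` is either one integer applied to every region or a mapping
    of region label to quota.  ``composition`` is the (male, female >= 21
    months, female kitten) split of the bag; the default is the observed
    harvest composition.  ``filling`` scales quotas to the fraction
    actually shot.
    """

    quota: int | dict = 0
    composition: tuple[float, float, float] = DEFAULT_COMPOSITION
    filling: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-8 or min(self.composition) < 0:
            raise ValueError("composition proportions must be >= 0 and sum to 1")
        if not 0.0 <= self.filling <= 1.0:
            raise ValueError("filling fraction must lie in [0, 1]")

    @property
    def label(self) -> str:
        if self.name is not None:
            return self.name
        if isinstance(self.quota, dict):
            return f"quota {sum(self.quota.values())} total"
        return f"quota {self.quota} per region"

    def region_quota(self, label: str) -> int:
        if isinstance(self.quota, dict):
            return int(self.quota.get(label, 0))
        return int(self.quota)


def allocate_harvest(
    total_quota: int,
    composition,
    n_current: np.ndarray,
    rng: np.random.Generator,
    *,
    filling: float = 1.0,
) -> np.ndarray:
    """Draw a female harvest vector (kitten, subadult, adult) from a quota.

    The bag is split male / female-older / female-kitten by a multinomial
    draw at the composition proportions; male removals leave the
    female-only state untouched.  Older females are divided between the
    subadult and adult stages by a Dirichlet-weighted draw at the current
    draw's stage composition.  Removals never exceed the (filled) quota.
    """
    composition = np.asarray(composition, dtype=float)
    if abs(composition.sum() - 1.0) > 1e-8 or composition.min() < 0:
        raise ValueError("composition proportions must be >= 0 and sum to 1")
    filled = int(total_quota)
    if filling < 1.0:
        filled = int(rng.binomial(filled, filling))
    males, fem_older, fem_kitten = rng.multinomial(filled, composition)
    h = np.zeros(3)
    h[0] = fem_kitten
    conc = np.maximum(np.asarray([n_current[1], n_current[2]], dtype=float), 1e-6)
    w = rng.dirichlet(conc)
    h[1] = rng.binomial(fem_older, w[0])
    h[2] = fem_older - h[1]
    return h


def goal_probabilities(draws, goal):
    """Empirical (P below, P within, P above) of draws against a goal.

    For an interval goal ``(low, high)``, "below" means strictly less
    than ``low`` and "above" strictly greater than ``high``; ties count
    as within.  For a single-value goal there is no "within" zone
    (returned as ``nan``): "below" is strictly less than the goal and
    everything else counts as meeting-or-exceeding it.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw set")
    if np.ndim(goal) == 0:
        below = float(np.mean(draws < float(goal)))
        return below, float("nan"), 1.0 - below
    low, high = float(goal[0]), float(goal[1])
    if high < low:
        raise ValueError("interval goal must be ordered")
    below = float(np.mean(draws < low))
    above = float(np.mean(draws > high))
    return below, 1.0 - below - above, above


@dataclass
class ForecastTable:
    """Forecast summaries plus the raw predictive draws behind them."""

    table: pd.DataFrame
    draws: dict = field(default_factory=dict)
    state_draws: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _collect_theta(chains):
    """Flatten chain draws into per-draw parameter arrays."""
    sc = {k: v.reshape(-1) for k, v in chains.scalars.items()}
    S = next(iter(sc.values())).shape[0]
    theta = {"phi1": sc["phi1"], "phi2": sc["phi2"], "sigma_p": sc["sigma_p"]}
    for base in ("r1", "r2", "rho", "F", "sigma_F"):
        arr = np.zeros((S, 3))
        for k in range(3):
            key = f"{base}[{k + 1}]"
            if key in sc:
                arr[:, k] = sc[key]
        theta[base] = arr
    return theta, S


def _matrices(theta, s):
    """Per-area projection matrices for draw ``s``."""
    phi1, phi2 = theta["phi1"][s], theta["phi2"][s]
    A = np.zeros((3, 3, 3))
    season = phi2**0.25
    mid2 = phi2**0.125
    for k in range(3):
        rho = theta["rho"][s, k]
        fec = season - rho * mid2
        A[k, 0, 1] = theta["r1"][s, k] * fec
        A[k, 0, 2] = theta["r2"][s, k] * fec
        A[k, 1, 0] = phi1 - rho * np.sqrt(phi1)
        A[k, 2, 1] = A[k, 2, 2] = phi2 - rho * np.sqrt(phi2)
    return A


def forecast(
    chains,
    data: MonitoringDataset,
    scenarios,
    horizon: int = 1,
    seed: int = 0,
    goals: dict | None = None,
) -> ForecastTable:
    """Forecast family groups 1..``horizon`` years beyond the data.

    ``scenarios`` is a list of :class:`HarvestScenario`; each is applied
    independently (the recorded harvest after the final census is always
    used for the first step, scenario quotas for subsequent steps).
    Goals default to ``data.goals`` for regions; area-level goals may be
    supplied under keys ``"area1"``, ``"area2"``, ``"area3"``.
    Summaries report the median, the 95 percent equal-tailed interval,
    and the probabilities of falling below / within / above the goal.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    if chains.logn is None:
        raise ValueError("forecasting needs stored latent-state draws")
    goals = dict(data.goals) if goals is None else dict(goals)
    theta, S = _collect_theta(chains)
    J = data.n_regions
    area_idx = data.region_to_area - 1
    n_last = np.exp(chains.logn[..., -1]).reshape(S, 3, J)
    h_known = data.h[:, :, -1]  # harvest pulse already taken after census T

    rows = []
    all_draws = {}
    all_states = {}
    for scenario in scenarios:
        rng = np.random.default_rng(seed)
        fg = np.zeros((S, J, horizon))
        states = np.zeros((S, 3, J, horizon))
        for s in range(S):
            A = _matrices(theta, s)
            sigma_p = theta["sigma_p"][s]
            n = n_last[s].copy()
            for step in range(horizon):
                for j in range(J):
                    k = area_idx[j]
                    if step == 0:
                        h = h_known[:, j]
                    else:
                        h = allocate_harvest(
                            scenario.region_quota(data.regions[j]),
                            scenario.composition,
                            n[:, j],
                            rng,
                            filling=scenario.filling,
                        )
                    src = np.maximum(n[:, j] - h, STATE_FLOOR)
                    mu = np.maximum(A[k] @ src, _RATE_FLOOR)
                    n[:, j] = np.exp(rng.normal(np.log(mu), sigma_p))
                states[s, :, :, step] = n
                for k in np.unique(area_idx):
                    spec = beta_from_moments(
                        float(np.clip(theta["F"][s, k], 1e-3, 1 - 1e-3)),
                        float(
                            np.clip(
                                theta["sigma_F"][s, k],
                                1e-4,
                                0.99
                                * np.sqrt(
                                    theta["F"][s, k] * (1 - theta["F"][s, k])
                                ),
                            )
                        ),
                    )
                    f_new = rng.beta(spec.alpha, spec.beta)
                    for j in np.flatnonzero(area_idx == k):
                        fg[s, j, step] = rng.poisson(f_new * n[:, j].sum())

        groups = [(label, [j]) for j, label in enumerate(data.regions)]
        for k in np.unique(area_idx):
            groups.append(
                (f"area{k + 1}", list(np.flatnonzero(area_idx == k)))
            )
        for step in range(horizon):
            for label, members in groups:
                draws = fg[:, members, step].sum(axis=1)
                all_draws[(scenario.label, step + 1, label)] = draws
                all_states[(scenario.label, step + 1, label)] = states[
                    :, :, members, step
                ].sum(axis=2)
                goal = goals.get(label)
                if goal is not None:
                    below, within, above = goal_probabilities(draws, goal)
                else:
                    below = within = above = float("nan")
                lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
                rows.append(
                    {
                        "scenario": scenario.label,
                        "horizon": step + 1,
                        "group": label,
                        "harvest": (
                            0
                            if step == 0
                            else sum(
                                scenario.region_quota(data.regions[j])
                                for j in members
                            )
                        ),
                        "median": med,
                        "q2.5": lo,
                        "q97.5": hi,
                        "P_below": below,
                        "P_within": within,
                        "P_above": above,
                    }
                )
    return ForecastTable(
        table=pd.DataFrame(rows), draws=all_draws, state_draws=all_states
    )
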