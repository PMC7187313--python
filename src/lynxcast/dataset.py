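"""Monitoring dataset container: family-group counts, harvest, quotas.

The monitoring unit is the *family group* (an adult female with dependent
young), counted each winter by verified snow-tracking.  Counts are held on
a common year axis across management regions; regions may start later than
the axis origin (their states are undefined before the first census) and
individual region-years may be missing (the observation term is simply
skipped while the latent state propagates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MonitoringDataset", "N_STAGES", "AREA_NAMES"]

N_STAGES = 3
AREA_NAMES = {1: "northern Sweden", 2: "southern Norway", 3: "northern Norway"}


@dataclass
class MonitoringDataset:
    """Observed inputs to the state-space model.

    Attributes
    ----------
    regions
        Region labels, length ``J``.
    region_to_area
        Geographical area code per region, each in {1, 2, 3}.
    years
        Consecutive census years (global axis), length ``T``.
    y
        Family-group counts, shape ``(J, T)``; ``-1`` marks a missing
        region-year.
    h
        Female harvest removals by stage, shape ``(3, J, T)``; ``h[:, j, t]``
        is the harvest pulse immediately following census ``t``.
    h_male
        Male removals per region-year, shape ``(J, T)`` (kept for quota
        bookkeeping; males are outside the female-only model).
    quota
        Total set quota per region-year, shape ``(J, T)``; ``-1`` if unset.
    goals
        Management objective per region label: a single family-group value
        or an ``(low, high)`` interval.
    """

    regions: list[str]
    region_to_area: np.ndarray
    years: np.ndarray
    y: np.ndarray
    h: np.ndarray
    h_male: np.ndarray | None = None
    quota: np.ndarray | None = None
    goals: dict[str, float | tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_to_area = np.asarray(self.region_to_area, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.h = np.asarray(self.h, dtype=float)
        if self.h_male is None:
            self.h_male = np.zeros_like(self.y, dtype=float)
        if self.quota is None:
            self.quota = np.full_like(self.y, -1)
        self.validate()

    # -- basic dimensions ------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def areas(self) -> np.ndarray:
        """Sorted unique area codes present in the dataset."""
        return np.unique(self.region_to_area)

    @property
    def obs_mask(self) -> np.ndarray:
        """Boolean ``(J, T)``: region-years with an observed count."""
        return self.y >= 0

    @property
    def start_index(self) -> np.ndarray:
        """First year index with data, per region."""
        return np.array([int(np.argmax(row)) for row in self.obs_mask])

    @property
    def state_mask(self) -> np.ndarray:
        """Boolean ``(J, T)``: region-years with a defined latent state."""
        mask = np.zeros_like(self.obs_mask)
        for j, s in enumerate(self.start_index):
            mask[j, s:] = True
        return mask

    def area_year_mask(self) -> np.ndarray:
        """Boolean ``(K, T)`` over area codes 1..3: area active that year."""
        out = np.zeros((3, self.n_years), dtype=bool)
        state = self.state_mask
        for j, k in enumerate(self.region_to_area):
            out[k - 1] |= state[j]
        return out

    def regions_in_area(self, area: int) -> np.ndarray:
        return np.flatnonzero(self.region_to_area == area)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        J, T = self.n_regions, self.n_years
        if self.region_to_area.shape != (J,):
            raise ValueError("region_to_area must have one entry per region")
        if not np.all(np.isin(self.region_to_area, (1, 2, 3))):
            raise ValueError("area codes must be in {1, 2, 3}")
        if T < 2:
            raise ValueError("need at least 2 census years")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        if self.y.shape != (J, T):
            raise ValueError(f"y must have shape {(J, T)}, got {self.y.shape}")
        if self.h.shape != (N_STAGES, J, T):
            raise ValueError(
                f"h must have shape {(N_STAGES, J, T)}, got {self.h.shape}"
            )
        if np.any(self.h < 0):
            raise ValueError("harvest removals must be nonnegative")
        if not np.all(self.obs_mask.any(axis=1)):
            missing = [r for r, m in zip(self.regions, self.obs_mask) if not m.any()]
            raise ValueError(f"regions with no observations: {missing}")
        for j, s in enumerate(self.start_index):
            if self.obs_mask[j, s:].sum() < 2:
                raise ValueError(
                    f"region {self.regions[j]!r} has fewer than 2 observed years"
                )
        for label, goal in self.goals.items():
            vals = np.atleast_1d(np.asarray(goal, dtype=float))
            if np.any(vals <= 0):
                raise ValueError(f"goal for {label!r} must be positive")

    # -- convenience -----------------------------------------------------

    def area_counts(self, area: int) -> np.ndarray:
        """Observed family groups summed over a geographical area per year.

        Years where any member region is missing are returned as ``-1``.
        """
        rows = self.y[self.regions_in_area(area)]
        total = rows.sum(axis=0)
        total[np.any(rows < 0, axis=0)] = -1
        return total
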