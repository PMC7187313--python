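"""CSV readers/writers and report generation.

One tabular dialect is used throughout: UTF-8, comma-delimited CSV with a
header row.  The monitoring table has one row per region-year:

    country,region,area,year,family_groups,harvest_female_kitten,
    harvest_female_older,harvest_male,quota

``family_groups`` may be empty for a missing census; harvest columns
default to 0; ``quota`` may be empty.  Because the harvest data
distinguish female kittens from older females but not subadults from
adults, older-female removals are split between the subadult and adult
stages at the stable-age ratio implied by the area's prior-mean vital
rates when a file is read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MonitoringDataset
from .demography import VitalRates, build_projection_matrix, stable_age_distribution
from .quota import QuotaSeries

__all__ = [
    "MONITORING_COLUMNS",
    "read_monitoring_csv",
    "write_monitoring_csv",
    "read_quota_csv",
    "quota_series_from_dataset",
    "report",
]

logger = logging.getLogger(__name__)

MONITORING_COLUMNS = [
    "country",
    "region",
    "area",
    "year",
    "family_groups",
    "harvest_female_kitten",
    "harvest_female_older",
    "harvest_male",
    "quota",
]

# prior-mean vital rates per area used only for the older-female stage split
_SPLIT_RATES = {
    1: VitalRates(phi1=0.900, phi2=0.965, r1=0.222, r2=0.393, rho=0.0),
    2: VitalRates(phi1=0.900, phi2=0.965, r1=0.500, r2=0.500, rho=0.0),
    3: VitalRates(phi1=0.900, phi2=0.965, r1=0.222, r2=0.393, rho=0.0),
}


def _older_split(area: int) -> float:
    """Subadult share of older-female harvest for an area."""
    sad = stable_age_distribution(build_projection_matrix(_SPLIT_RATES[area]))
    return float(sad[1] / (sad[1] + sad[2]))


class MonitoringParseError(ValueError):
    pass


def read_monitoring_csv(path, goals: dict | None = None) -> MonitoringDataset:
    """Load and validate a monitoring table into a :class:`MonitoringDataset`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"country": str, "region": str})
    unknown = [c for c in frame.columns if c not in MONITORING_COLUMNS]
    missing = [c for c in MONITORING_COLUMNS if c not in frame.columns]
    if unknown or missing:
        raise MonitoringParseError(
            f"{path}: header mismatch (unknown={unknown}, missing={missing}); "
            f"expected {MONITORING_COLUMNS}"
        )
    for col in ("family_groups", "harvest_female_kitten", "harvest_female_older",
                "harvest_male", "quota"):
        bad = frame.index[frame[col].fillna(0) < 0]
        if len(bad) and col != "family_groups":
            raise MonitoringParseError(
                f"{path}: negative {col} at line {bad[0] + 2}"
            )
        if len(bad):
            raise MonitoringParseError(
                f"{path}: family_groups = "
                f"{frame.loc[bad[0], col]} at line {bad[0] + 2}; "
                "leave the cell empty for a missing census"
            )
    if not frame["area"].isin((1, 2, 3)).all():
        line = frame.index[~frame["area"].isin((1, 2, 3))][0] + 2
        raise MonitoringParseError(f"{path}: area code outside {{1,2,3}} at line {line}")

    regions = list(dict.fromkeys(frame["region"]))
    region_area = {}
    for label, sub in frame.groupby("region", sort=False):
        areas = sub["area"].unique()
        if len(areas) != 1:
            raise MonitoringParseError(
                f"{path}: region {label!r} mapped to multiple areas {areas}"
            )
        region_area[label] = int(areas[0])
        years = np.sort(sub["year"].to_numpy())
        if len(years) != len(set(years)):
            raise MonitoringParseError(f"{path}: duplicate year for region {label!r}")
        if np.any(np.diff(years) != 1):
            raise MonitoringParseError(
                f"{path}: non-consecutive years for region {label!r}"
            )

    y0, y1 = int(frame["year"].min()), int(frame["year"].max())
    years = np.arange(y0, y1 + 1)
    J, T = len(regions), len(years)
    y = np.full((J, T), -1, dtype=int)
    h = np.zeros((3, J, T))
    h_male = np.zeros((J, T))
    quota = np.full((J, T), -1, dtype=int)
    for _, row in frame.iterrows():
        j = regions.index(row["region"])
        t = int(row["year"]) - y0
        fg = row["family_groups"]
        y[j, t] = int(fg) if pd.notna(fg) else -1
        split = _older_split(region_area[row["region"]])
        older = float(row["harvest_female_older"]) if pd.notna(
            row["harvest_female_older"]) else 0.0
        h[0, j, t] = float(row["harvest_female_kitten"]) if pd.notna(
            row["harvest_female_kitten"]) else 0.0
        h[1, j, t] = older * split
        h[2, j, t] = older * (1.0 - split)
        h_male[j, t] = float(row["harvest_male"]) if pd.notna(
            row["harvest_male"]) else 0.0
        quota[j, t] = int(row["quota"]) if pd.notna(row["quota"]) else -1

    return MonitoringDataset(
        regions=regions,
        region_to_area=np.array([region_area[r] for r in regions]),
        years=years,
        y=y,
        h=h,
        h_male=h_male,
        quota=quota,
        goals=goals or {},
    )


def write_monitoring_csv(data: MonitoringDataset, path) -> None:
    """Write a dataset back to the monitoring CSV dialect.

    The subadult/adult harvest stages are collapsed into the
    ``harvest_female_older`` column, so a write -> read round trip
    preserves counts, quotas, kitten harvest, and the older-female total
    (the stage split is re-derived on read).
    """
    country_of = {1: "Sweden", 2: "Norway", 3: "Norway"}
    rows = []
    for j, label in enumerate(data.regions):
        area = int(data.region_to_area[j])
        for t, year in enumerate(data.years):
            if not data.state_mask[j, t] and data.y[j, t] < 0:
                continue
            rows.append(
                {
                    "country": country_of[area],
                    "region": label,
                    "area": area,
                    "year": int(year),
                    "family_groups": (
                        int(data.y[j, t]) if data.y[j, t] >= 0 else None
                    ),
                    "harvest_female_kitten": float(data.h[0, j, t]),
                    "harvest_female_older": float(data.h[1, j, t] + data.h[2, j, t]),
                    "harvest_male": float(data.h_male[j, t]),
                    "quota": (
                        int(data.quota[j, t]) if data.quota[j, t] >= 0 else None
                    ),
                }
            )
    pd.DataFrame(rows, columns=MONITORING_COLUMNS).to_csv(path, index=False)


def read_quota_csv(path) -> QuotaSeries:
    """Read a standalone two-column quota table.

    Columns: ``census_fg_prev_year, quota``.
    """
    frame = pd.read_csv(path)
    expected = ["census_fg_prev_year", "quota"]
    if list(frame.columns) != expected:
        raise MonitoringParseError(
            f"{path}: expected columns {expected}, got {list(frame.columns)}"
        )
    return QuotaSeries(
        x=frame["census_fg_prev_year"].to_numpy(), q=frame["quota"].to_numpy()
    )


def quota_series_from_dataset(data: MonitoringDataset, areas=None) -> QuotaSeries:
    """Aggregate (previous census, quota) pairs over a group of areas.

    Pairs are kept only for years where every member region reports both
    the previous census and a set quota.
    """
    areas = list(areas) if areas is not None else list(data.areas)
    members = [
        j for j in range(data.n_regions) if data.region_to_area[j] in areas
    ]
    xs, qs = [], []
    for t in range(1, data.n_years):
        y_prev = data.y[members, t - 1]
        q_now = data.quota[members, t]
        if np.all(y_prev >= 0) and np.all(q_now >= 0):
            xs.append(int(y_prev.sum()))
            qs.append(int(q_now.sum()))
    return QuotaSeries(x=np.array(xs, dtype=int), q=np.array(qs, dtype=int))


def report(obj, out_dir, *, log_lines=None) -> list[Path]:
    """Write summary CSVs plus a plain-text run log for a result object.

    Accepts posterior chains, a forecast table, or a quota posterior; the
    run log records the seed, settings, and convergence flags so a run
    can be audited and repeated.
    """
    from .forecast import ForecastTable
    from .inference import PosteriorChains
    from .quota import QuotaPosterior

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    log = list(log_lines or [])
    if isinstance(obj, PosteriorChains):
        path = out / "posterior_summary.csv"
        obj.summary().to_csv(path)
        written.append(path)
        obj.save(out / "chains")
        log.append(f"seed: {obj.meta.get('seed')}")
        log.append(f"settings: {obj.meta.get('settings')}")
        log.append(f"converged: {obj.meta.get('converged', 'n/a')}")
        log.append(f"max_psrf_upper: {obj.meta.get('max_psrf_upper', 'n/a')}")
    elif isinstance(obj, ForecastTable):
        path = out / "forecast.csv"
        obj.to_csv(path)
        written.append(path)
        log.append(f"scenarios: {sorted(set(obj.table['scenario']))}")
    elif isinstance(obj, QuotaPosterior):
        path = out / "quota_summary.csv"
        obj.summary().to_csv(path)
        written.append(path)
        log.append(f"model: {obj.model}")
        log.append(f"meta: {obj.meta}")
    else:
        raise TypeError(f"cannot report object of type {type(obj)!r}")
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(str(line) for line in log) + "\n")
    written.append(log_path)
    return written
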