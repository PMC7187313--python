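"""Predictive forecasting: goal probabilities, harvest allocation, limits."""

import numpy as np
import pytest

import lynxcast as lx
from lynxcast.dataset import MonitoringDataset
from lynxcast.forecast import allocate_harvest, goal_probabilities


class TestGoalProbabilities:
    def test_equal_thirds_toy_set(self):
        below, within, above = goal_probabilities([60, 70, 130], (68, 127))
        assert (below, within, above) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3)
        )

    def test_all_draws_below(self):
        assert goal_probabilities([1, 2, 3], (68, 127)) == (1.0, 0.0, 0.0)

    def test_ties_count_as_within(self):
        below, within, above = goal_probabilities([68, 127], (68, 127))
        assert (below, within, above) == (0.0, 1.0, 0.0)

    def test_single_value_goal_splits_below_above(self):
        below, within, above = goal_probabilities([10, 20, 40, 50], 33.0)
        assert below == 0.5 and above == 0.5 and np.isnan(within)

    def test_lognormal_median_threshold(self, rng):
        draws = rng.lognormal(0.0, 1.0, size=100_000)
        below, _, above = goal_probabilities(draws, 1.0)
        assert below == pytest.approx(0.5, abs=0.01)

    def test_invariant_to_order_and_sums_to_one(self, rng):
        draws = rng.uniform(0, 200, size=501)
        a = goal_probabilities(draws, (50, 150))
        b = goal_probabilities(draws[::-1], (50, 150))
        assert a == b
        assert sum(a) == pytest.approx(1.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            goal_probabilities([], (1, 2))


class TestAllocateHarvest:
    def test_all_older_female_composition(self, rng):
        h = allocate_harvest(10, (0.0, 1.0, 0.0), np.array([5.0, 4.0, 12.0]), rng)
        assert h[0] == 0 and h[1] + h[2] == 10

    def test_expected_class_totals_under_default_composition(self, rng):
        kittens, older = [], []
        n = np.array([8.0, 5.0, 15.0])
        for _ in range(4000):
            h = allocate_harvest(10, lx.simulate.DEFAULT_COMPOSITION, n, rng)
            kittens.append(h[0])
            older.append(h[1] + h[2])
        assert np.mean(kittens) == pytest.approx(0.9, abs=0.05)
        assert np.mean(older) == pytest.approx(3.4, abs=0.1)

    def test_total_removals_never_exceed_quota(self, rng):
        n = np.array([3.0, 2.0, 9.0])
        for quota in (0, 1, 7, 25):
            for _ in range(50):
                h = allocate_harvest(quota, (0.57, 0.34, 0.09), n, rng)
                assert h.sum() <= quota

    def test_filling_fraction_reduces_expected_take(self, rng):
        n = np.array([5.0, 5.0, 15.0])
        full = [
            allocate_harvest(20, (0.0, 1.0, 0.0), n, rng).sum()
            for _ in range(800)
        ]
        partial = [
            allocate_harvest(20, (0.0, 1.0, 0.0), n, rng, filling=0.5).sum()
            for _ in range(800)
        ]
        assert np.mean(partial) == pytest.approx(0.5 * np.mean(full), rel=0.1)

    def test_bad_composition_rejected(self, rng):
        with pytest.raises(ValueError):
            allocate_harvest(5, (0.5, 0.2, 0.2), np.ones(3), rng)


def _single_draw_chains(data, *, sigma_p, rho, n_last, phi1=0.90, phi2=0.96,
                        r1=0.3, r2=0.4):
    """Posterior chains holding exactly one synthetic draw."""
    J = data.n_regions
    scalars = {
        "phi1": [[phi1]], "phi2": [[phi2]], "sigma_p": [[sigma_p]],
    }
    for k in (1, 2, 3):
        scalars[f"r1[{k}]"] = [[r1]]
        scalars[f"r2[{k}]"] = [[r2]]
        scalars[f"rho[{k}]"] = [[rho]]
        scalars[f"F[{k}]"] = [[0.31]]
        scalars[f"sigma_F[{k}]"] = [[0.023]]
    scalars = {k: np.asarray(v, dtype=float) for k, v in scalars.items()}
    logn = np.zeros((1, 1, 3, J, data.n_years))
    logn[0, 0, :, :, -1] = np.log(n_last)
    f = np.full((1, 1, 3, data.n_years), 0.31)
    return lx.PosteriorChains(scalars=scalars, f=f, logn=logn, meta={})


def _bare_dataset(J=1, T=4):
    return MonitoringDataset(
        regions=[f"R{j}" for j in range(J)],
        region_to_area=np.ones(J, dtype=int),
        years=np.arange(2000, 2000 + T),
        y=np.full((J, T), 20),
        h=np.zeros((3, J, T)),
    )


class TestForecast:
    def test_deterministic_limit_equals_projection(self):
        data = _bare_dataset()
        n_last = np.array([[10.0], [6.0], [20.0]])[:, 0]
        chains = _single_draw_chains(
            data, sigma_p=0.0, rho=0.0, n_last=n_last[:, None]
        )
        table = lx.forecast(
            chains, data, [lx.HarvestScenario(quota=0)], horizon=1, seed=0
        )
        A = lx.build_projection_matrix(
            lx.VitalRates(0.90, 0.96, 0.3, 0.4, 0.0)
        )
        got = table.state_draws[("quota 0 per region", 1, "R0")][0]
        assert got == pytest.approx(A @ n_last, abs=1e-10)

    def test_growth_gives_nondecreasing_medians_without_harvest(self):
        data = _bare_dataset()
        n_last = np.array([[10.0], [6.0], [20.0]])
        chains = _single_draw_chains(
            data, sigma_p=0.01, rho=0.0, n_last=n_last, r1=0.45, r2=0.5
        )
        table = lx.forecast(
            chains, data, [lx.HarvestScenario(quota=0)], horizon=3, seed=1
        )
        med = [
            np.median(table.state_draws[("quota 0 per region", h, "R0")].sum(axis=1))
            for h in (1, 2, 3)
        ]
        assert med[0] <= med[1] <= med[2]

    def test_known_final_harvest_used_for_first_step(self):
        data = _bare_dataset()
        data.h[:, 0, -1] = [0.0, 2.0, 4.0]  # recorded post-census harvest
        n_last = np.array([[10.0], [6.0], [20.0]])[:, 0]
        chains = _single_draw_chains(
            data, sigma_p=0.0, rho=0.0, n_last=n_last[:, None]
        )
        table = lx.forecast(
            chains, data, [lx.HarvestScenario(quota=0)], horizon=1, seed=0
        )
        A = lx.build_projection_matrix(lx.VitalRates(0.90, 0.96, 0.3, 0.4, 0.0))
        got = table.state_draws[("quota 0 per region", 1, "R0")][0]
        assert got == pytest.approx(A @ (n_last - np.array([0.0, 2.0, 4.0])))

    def test_invalid_horizon_rejected(self, small_fit):
        chains, data, _ = small_fit
        with pytest.raises(ValueError):
            lx.forecast(chains, data, [lx.HarvestScenario(quota=0)], horizon=0)

    def test_goal_columns_and_interval_order(self, small_fit):
        chains, data, _ = small_fit
        goals = {"A1R1": (10, 60), "area2": 30.0}
        table = lx.forecast(
            chains, data, [lx.HarvestScenario(quota=2)], horizon=2, seed=4,
            goals=goals,
        ).table
        assert {"scenario", "horizon", "group", "median", "q2.5", "q97.5",
                "P_below", "P_within", "P_above"} <= set(table.columns)
        assert (table["q2.5"] <= table["median"]).all()
        assert (table["median"] <= table["q97.5"]).all()
        row = table[(table["group"] == "A1R1") & (table["horizon"] == 1)].iloc[0]
        assert row["P_below"] + row["P_within"] + row["P_above"] == pytest.approx(1.0)
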