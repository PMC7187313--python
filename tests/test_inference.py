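"""Sampler correctness: determinism, support, and the conjugate reduction."""

import math

import numpy as np
import pytest
from scipy import stats

import lynxcast as lx
from lynxcast.model import LynxModel, ParameterState


def _tiny_settings(seed=11):
    return lx.FitSettings(n_chains=1, n_iter=700, n_burnin=350, thin=5, seed=seed)


class TestDeterminism:
    def test_identical_seed_gives_identical_chains(self, small_data):
        data, _ = small_data
        a = lx.fit(data, settings=_tiny_settings())
        b = lx.fit(data, settings=_tiny_settings())
        for name in a.scalar_names:
            assert np.array_equal(a.scalars[name], b.scalars[name]), name
        assert np.array_equal(a.logn, b.logn)

    def test_different_seed_gives_different_chains(self, small_data):
        data, _ = small_data
        a = lx.fit(data, settings=_tiny_settings(seed=11))
        b = lx.fit(data, settings=_tiny_settings(seed=12))
        assert not np.array_equal(a.scalars["sigma_p"], b.scalars["sigma_p"])


class TestPosteriorChains:
    def test_draw_supports_and_shapes(self, small_fit):
        chains, data, _ = small_fit
        C, D = chains.n_chains, chains.n_draws
        for k in (1, 2, 3):
            rho = chains.scalars[f"rho[{k}]"]
            assert rho.shape == (C, D)
            assert np.all((rho >= 0) & (rho <= 1))
        sp = chains.scalars["sigma_p"]
        assert np.all((sp > 0) & (sp < 4))
        assert chains.f.shape == (C, D, 3, data.n_years)
        assert np.all((chains.f > 0) & (chains.f < 1))
        assert chains.logn.shape == (C, D, 3, data.n_regions, data.n_years)
        psi = np.stack([chains.scalars[f"psi[{i}]"] for i in (1, 2, 3)])
        assert psi.sum(axis=0) == pytest.approx(np.ones((C, D)))

    def test_summary_table_schema(self, small_fit):
        chains, _, _ = small_fit
        table = chains.summary()
        assert list(table.columns) == ["mean", "sd", "q2.5", "median", "q97.5"]
        assert {"phi1", "phi2", "sigma_p", "rho[1]", "lambda[1]"} <= set(
            table.index
        )
        assert (table["q2.5"] <= table["median"]).all()
        assert (table["median"] <= table["q97.5"]).all()

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        chains, _, _ = small_fit
        chains.save(tmp_path / "chains")
        loaded = lx.PosteriorChains.load(tmp_path / "chains")
        assert loaded.n_chains == chains.n_chains
        for name in chains.scalar_names:
            assert loaded.scalars[name] == pytest.approx(chains.scalars[name])
        assert loaded.meta["seed"] == chains.meta["seed"]


class TestConjugateReduction:
    """With states and all other parameters frozen, the sigma_p conditional
    has a closed form; a plain Metropolis chain driven by the model's joint
    density must reproduce it."""

    def test_sigma_p_conditional_matches_closed_form(self, small_data):
        data, truth = small_data
        model = LynxModel(data, lx.default_prior_set())
        vr = truth["vital_rates"][0]
        state = ParameterState(
            phi1=vr.phi1,
            phi2=vr.phi2,
            r1=np.array([v.r1 for v in truth["vital_rates"]]),
            r2=np.array([v.r2 for v in truth["vital_rates"]]),
            rho=truth["rho"].copy(),
            F=truth["F"].copy(),
            sigma_F=truth["sigma_F"].copy(),
            sigma_p=truth["sigma_p"],
            psi=np.array([0.2, 0.2, 0.6]),
            f=np.clip(truth["f"], 0.01, 0.99),
            logn=np.log(np.maximum(truth["n"], 1e-6)),
        )
        model.refresh_initial_states(state)

        # closed form: density prop. to sigma^-n exp(-SS / (2 sigma^2)),
        # truncated to the uniform prior support
        A = model.area_matrices(state)
        mu = model.project_all(state, A)
        resid = state.logn[:, :, 1:] - np.log(np.maximum(mu[:, :, :-1], 1e-10))
        mask = model.proc_mask[:, 1:]
        ss = float(np.sum((resid**2) * mask[None]))
        n_terms = int(3 * mask.sum())
        grid = np.linspace(1e-3, 1.2, 4000)
        log_dens = -n_terms * np.log(grid) - ss / (2 * grid**2)
        dens = np.exp(log_dens - log_dens.max())
        cdf_grid = np.cumsum(dens)
        cdf_grid /= cdf_grid[-1]

        # Metropolis chain over sigma_p via the model's joint density
        rng = np.random.default_rng(5)
        cur_lp = model.log_posterior(state)
        draws = []
        for it in range(6000):
            old = state.sigma_p
            state.sigma_p = old + rng.normal() * 0.02
            lp_new = model.log_posterior(state)
            if math.log(rng.uniform()) < lp_new - cur_lp:
                cur_lp = lp_new
            else:
                state.sigma_p = old
            if it >= 1000:
                draws.append(state.sigma_p)
        draws = np.asarray(draws[::10])

        result = stats.kstest(draws, lambda x: np.interp(x, grid, cdf_grid))
        assert result.pvalue > 0.01


class TestReducedSettings:
    def test_full_scale_defaults(self):
        s = lx.FitSettings()
        assert (s.n_chains, s.n_iter, s.n_burnin) == (3, 100_000, 50_000)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            lx.FitSettings(n_iter=100, n_burnin=200)
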