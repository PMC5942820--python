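"""Effect interpretation: half-life, standardized effects, and average
predictive comparisons against brute-force oracles."""

import numpy as np
import pytest
from scipy.special import expit

from snagfall.durability import DurabilityTable
from snagfall.effects import (
    average_predictive_comparison,
    average_with_imputation,
    default_scenarios,
    half_life,
    standardized_effect,
)
from snagfall.mcmc import PosteriorDraws
from snagfall.model import CovariateSpec, SnagDataset
from snagfall.simulate import parameter_recovery_config, simulate_survey

import pandas as pd


class TestHalfLife:
    def test_exact_values(self):
        assert half_life(0.5) == pytest.approx(1.0, abs=1e-12)
        assert half_life(0.25) == pytest.approx(0.5, abs=1e-12)

    def test_baseline_persistence_half_life(self):
        # log(0.5)/log(0.881) computed at high precision
        assert half_life(0.881) == pytest.approx(5.470876246685622, rel=1e-12)

    def test_inversion_identity(self):
        for p in np.arange(0.01, 1.0, 0.01):
            assert p ** half_life(p) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            half_life(p)


def _manual_draws(param_values: dict, n_draws=4, n_chains=1):
    """PosteriorDraws with every draw identical (degenerate posterior)."""
    names = list(param_values)
    row = np.array([param_values[nm] for nm in names], dtype=float)
    values = np.tile(row, (n_chains, n_draws, 1))
    return PosteriorDraws(names, values)


def _toy_setup(n_species=2, missing=(), dur=(1.0, 3.0), beta_dur=0.4):
    spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 2.0})
    n = 10
    rng = np.random.default_rng(1)
    ds = SnagDataset(
        rng.integers(0, 2, n),
        np.full(n, 5.0),
        rng.normal(0, 1, (n, 1)),
        np.zeros(n, dtype=int),
        np.zeros(n, dtype=int),
        rng.integers(0, n_species, n),
        np.ones(n, dtype=int),
        spec,
    )
    dur_col = [np.nan if i in missing else dur[i] for i in range(n_species)]
    table = DurabilityTable(
        pd.DataFrame(
            {
                "species": [f"sp{i}" for i in range(n_species)],
                "family": ["famA"] * n_species,
                "division": ["angiosperm"] * n_species,
                "durability": dur_col,
                "n_sources": [0 if i in missing else 1 for i in range(n_species)],
            }
        )
    )
    base = {
        "beta0": 0.8,
        "rho[AT]": -0.3,
        "beta_dur": beta_dur,
        "u[0]": 0.0,
        "v[0]": 0.0,
    }
    for i in range(n_species):
        base[f"w[{i}]"] = 0.1 * (i - 0.5)
    for i in missing:
        base[f"dur[sp{i}]"] = dur[i]
    return ds, spec, table, base


class TestStandardizedEffect:
    def test_divide_convention_arithmetic(self):
        draws = _manual_draws({"rho[AT]": 0.4})
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 2.0})
        eff = standardized_effect(draws, "AT", spec)
        assert eff.standardized_mean == pytest.approx(0.2)
        assert eff.convention == "divide"

    def test_unit_sd_is_identity(self):
        draws = _manual_draws({"rho[AT]": -0.73})
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 1.0})
        eff = standardized_effect(draws, "AT", spec)
        assert eff.standardized_mean == pytest.approx(eff.raw_mean)

    def test_multiply_convention_flag(self):
        draws = _manual_draws({"rho[AT]": 0.4})
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 2.0})
        eff = standardized_effect(draws, "AT", spec, convention="multiply")
        assert eff.standardized_mean == pytest.approx(0.8)

    def test_durability_effect_uses_per_draw_imputation_sd(self):
        ds, spec, table, base = _toy_setup(missing=(1,))
        # two distinct imputations across draws -> two distinct sds
        names = list(base)
        rows = []
        for dur1 in (2.0, 4.0):
            row = dict(base)
            row["dur[sp1]"] = dur1
            rows.append([row[nm] for nm in names])
        draws = PosteriorDraws(names, np.array(rows)[None, :, :])
        eff = standardized_effect(draws, "durability", spec,
                                  durability_table=table)
        sds = [np.std([1.0, d], ddof=1) for d in (2.0, 4.0)]
        expected = np.mean([0.4 / s for s in sds])
        assert eff.standardized_mean == pytest.approx(expected)


class TestAveragePredictiveComparison:
    def test_zero_perturbation_gives_zero(self):
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base)
        pc = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=0.0, n_posterior_draws=4,
        )
        assert np.all(pc.deltas == 0.0)

    def test_matches_brute_force_loop(self):
        """Fixed parameters, ten records: the APC equals a per-record loop
        evaluated by hand, to 1e-12."""
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base, n_draws=3)
        xi = 1.7
        pc = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=xi, n_posterior_draws=3,
        )
        acc = 0.0
        for i in range(len(ds)):
            eta = (
                base["beta0"]
                + base["rho[AT]"] * (ds.X[i, 0] - 0.0)
                + base[f"w[{ds.species[i]}]"]
            )
            acc += expit(eta + base["rho[AT]"] * xi) - expit(eta)
        assert pc.mean == pytest.approx(acc / len(ds), abs=1e-12)

    def test_opposite_perturbations_flip_sign(self):
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base)
        up = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=1.0, n_posterior_draws=4
        )
        down = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=-1.0, n_posterior_draws=4
        )
        assert np.sign(up.mean) == -np.sign(down.mean) != 0

    def test_identity_link_recovers_exact_linearity(self):
        """On the linear-response scale the APC collapses to rho * xi."""
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base)
        pc = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=2.5, response="linear",
            n_posterior_draws=4,
        )
        assert pc.mean == pytest.approx(base["rho[AT]"] * 2.5, abs=1e-12)

    def test_order_invariance(self):
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base)
        perm = np.random.default_rng(0).permutation(len(ds))
        pc1 = average_predictive_comparison(
            ds, draws, spec, focal="AT", xi=1.0, n_posterior_draws=4
        )
        pc2 = average_predictive_comparison(
            ds.subset(perm), draws, spec, focal="AT", xi=1.0,
            n_posterior_draws=4,
        )
        assert pc1.mean == pytest.approx(pc2.mean, abs=1e-12)

    def test_half_life_response_restricted_to_earliest_decay(self):
        ds, spec, table, base = _toy_setup()
        draws = _manual_draws(base)
        mixed = SnagDataset(
            ds.standing, ds.interval_years, ds.X, ds.phys_class, ds.cell,
            ds.species, np.r_[np.ones(5, int), np.full(5, 3)], spec,
        )
        pc = average_predictive_comparison(
            mixed, draws, spec, focal="AT", xi=1.0, response="half_life",
            n_posterior_draws=4,
        )
        only_dc1 = average_predictive_comparison(
            mixed.subset(mixed.decay_class == 1), draws, spec, focal="AT",
            xi=1.0, response="half_life", n_posterior_draws=4,
        )
        assert pc.mean == pytest.approx(only_dc1.mean, abs=1e-12)


class TestImputationAveraging:
    def test_reduces_to_plug_in_when_nothing_missing(self):
        ds, spec, table, base = _toy_setup(missing=())
        draws = _manual_draws(base)
        plug = average_predictive_comparison(
            ds, draws, spec, focal="durability", xi=-1.0,
            n_posterior_draws=4, durability_table=table,
        )
        avg = average_with_imputation(
            ds, draws, spec, xi=-1.0, n_draws=4, durability_table=table,
        )
        assert avg.mean == pytest.approx(plug.mean, abs=1e-12)
        assert avg.ci == pytest.approx(plug.ci, abs=1e-12)

    def test_degenerate_imputation_equals_plug_in(self):
        ds, spec, table, base = _toy_setup(missing=(1,))
        draws = _manual_draws(base)  # imputation posterior is a point mass
        plug = average_predictive_comparison(
            ds, draws, spec, focal="durability", xi=-1.0,
            n_posterior_draws=4, durability_table=table,
        )
        avg = average_with_imputation(
            ds, draws, spec, xi=-1.0, n_draws=4, durability_table=table,
        )
        assert avg.mean == pytest.approx(plug.mean, abs=1e-12)

    def test_imputation_uncertainty_widens_interval(self):
        """Spreading the imputed durability across draws cannot narrow the
        APC interval relative to plugging in its posterior mean."""
        ds, spec, table, base = _toy_setup(missing=(1,), beta_dur=0.8)
        names = list(base)
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(400):
            row = dict(base)
            dur1 = float(np.clip(rng.normal(2.5, 1.0), 0, 4))
            row["dur[sp1]"] = dur1
            # the species effect co-varies with its durability draw, as in a
            # genuine joint posterior (residual held fixed)
            row["w[1]"] = 0.05 + 0.8 * (dur1 - 1.0)
            rows.append([row[nm] for nm in names])
        draws = PosteriorDraws(names, np.array(rows)[None, :, :])
        plug = average_predictive_comparison(
            ds, draws, spec, focal="durability", xi=-1.0,
            n_posterior_draws=400, durability_table=table,
        )
        avg = average_with_imputation(
            ds, draws, spec, xi=-1.0, n_draws=400, durability_table=table,
        )
        width = lambda ci: ci[1] - ci[0]
        assert width(avg.ci) >= width(plug.ci) - 1e-12


class TestDefaultScenarios:
    def test_mid_century_perturbations(self):
        scen = {s["focal"]: s for s in default_scenarios()}
        assert scen["AT"]["xi"] == 2.4 and scen["AT"]["units"] == "deg C"
        assert scen["DIA"]["xi"] == 3.5
        assert scen["TPH"]["xi"] == -100.0
        assert scen["durability"]["xi"] == -1.0


class TestOnFittedDraws:
    def test_apc_sign_matches_fitted_effect(self):
        """End-to-end: a negative fitted temperature effect yields a negative
        annual-probability APC for warming."""
        sim = simulate_survey(parameter_recovery_config(seed=12, n_snags=1200))
        from snagfall.mcmc import ChainConfig, run_chains

        draws = run_chains(
            sim.dataset, sim.grid, sim.spec,
            ChainConfig(n_chains=2, n_iterations=1500, burn_in=400, thin=5,
                        base_seed=2),
            sim.durability_table,
        )
        pc = average_predictive_comparison(
            sim.dataset, draws, sim.spec, focal="AT", xi=2.4,
            n_posterior_draws=400, durability_table=sim.durability_table,
        )
        assert pc.mean < 0
        hl = average_predictive_comparison(
            sim.dataset, draws, sim.spec, focal="AT", xi=2.4,
            response="half_life", n_posterior_draws=400,
            durability_table=sim.durability_table,
        )
        assert hl.mean < 0
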