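"""Deterministic model-side computations: linear predictor, likelihood,
CAR conditionals, durability transforms, priors."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from snagfall.model import (
    NEG_INF,
    CovariateSpec,
    ModelParameters,
    SnagDataset,
    SnagRecord,
    SpatialGrid,
    annual_persistence,
    car_conditional,
    durability_logit,
    icar_logpdf,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
    species_mean,
    standing_probability,
)
from conftest import make_tiny_model


def _record(covariates, **kw):
    defaults = dict(
        standing=1, interval_years=5.0, phys_class=0, cell=0, species=0
    )
    defaults.update(kw)
    return SnagRecord(covariates=covariates, **defaults)


class TestLinearPredictor:
    def test_all_terms_vanish_at_centers(self):
        spec = CovariateSpec(("AT",), {"AT": 10.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=1.5, rho=np.array([0.7]), u=np.zeros(1), sigma_p=1.0,
            v=np.zeros(1), sigma_g=1.0, w=np.zeros(1), sigma_s=1.0,
            durability=make_tiny_model()[1].durability,
        )
        rec = _record({"AT": 10.0})
        assert linear_predictor(rec, params, spec) == pytest.approx(1.5)

    def test_sum_of_named_terms(self):
        spec = CovariateSpec(("AT",), {"AT": 1.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=0.0, rho=np.array([0.5]), u=np.array([0.2]), sigma_p=1.0,
            v=np.array([-0.1]), sigma_g=1.0, w=np.array([0.3]), sigma_s=1.0,
            durability=make_tiny_model()[1].durability,
        )
        rec = _record({"AT": 3.0})
        assert linear_predictor(rec, params, spec) == pytest.approx(1.4)

    def test_baseline_inverse_logit_gives_fitted_persistence(self):
        # the intercept alone reproduces the baseline annual probability
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=float(logit(0.881)), rho=np.array([0.0]), u=np.zeros(1),
            sigma_p=1.0, v=np.zeros(1), sigma_g=1.0, w=np.zeros(1),
            sigma_s=1.0, durability=make_tiny_model()[1].durability,
        )
        rec = _record({"AT": 0.0})
        assert annual_persistence(rec, params, spec) == pytest.approx(0.881)

    def test_missing_covariate_is_named(self):
        dataset, params, spec, grid, mask = make_tiny_model()
        with pytest.raises(ValueError, match="AT"):
            SnagDataset.from_records([_record({"WND": 1.0})], spec)

    def test_out_of_range_index_rejected(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        bad = SnagRecord(
            standing=1, interval_years=5.0, covariates={"AT": 10.0},
            phys_class=9, cell=0, species=0,
        )
        with pytest.raises(ValueError, match="phys_class"):
            linear_predictor(bad, params, spec)


class TestAnnualPersistence:
    @pytest.mark.parametrize(
        "eta,expected", [(0.0, 0.5), (1.0, 1.0 / (1.0 + math.exp(-1.0)))]
    )
    def test_inverse_logit_values(self, eta, expected):
        assert expit(eta) == pytest.approx(expected, abs=1e-12)

    def test_strictly_inside_unit_interval(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        p = annual_persistence(dataset, params, spec)
        assert np.all(p > 0) and np.all(p < 1)

    def test_monotone_in_positive_covariate(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        params = params.copy()
        params.rho = np.array([0.4])
        base = _record({"AT": 10.0})
        higher = _record({"AT": 11.0})
        assert annual_persistence(higher, params, spec) > annual_persistence(
            base, params, spec
        )


class TestStandingProbability:
    def test_identity_at_one_year(self):
        assert standing_probability(0.5, 1.0) == pytest.approx(0.5)

    def test_fractional_interval_square_root(self):
        assert standing_probability(0.25, 0.5) == pytest.approx(0.5)

    def test_five_year_baseline(self):
        # 0.881**5, high-precision exponentiation
        assert standing_probability(0.881, 5.0) == pytest.approx(
            0.530737216068401, rel=1e-12
        )
        assert round(standing_probability(0.881, 5.0), 4) == 0.5307

    def test_interval_additivity(self, rng):
        for _ in range(50):
            p = rng.uniform(0.01, 0.99)
            t1, t2 = rng.uniform(0.1, 10.0, size=2)
            assert standing_probability(p, t1 + t2) == pytest.approx(
                standing_probability(p, t1) * standing_probability(p, t2),
                abs=1e-12,
            )

    @pytest.mark.parametrize("p,t", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0), (-0.1, 2.0)])
    def test_domain_errors(self, p, t):
        with pytest.raises(ValueError):
            standing_probability(p, t)


class TestLogLikelihood:
    def _single(self, standing, p, t):
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=float(logit(p)), rho=np.array([0.0]), u=np.zeros(1),
            sigma_p=1.0, v=np.zeros(1), sigma_g=1.0, w=np.zeros(1),
            sigma_s=1.0, durability=make_tiny_model()[1].durability,
        )
        ds = SnagDataset.from_records(
            [_record({"AT": 0.0}, standing=standing, interval_years=t)], spec
        )
        return log_likelihood(ds, params, spec)

    def test_standing_record(self):
        assert self._single(1, 0.8, 2.0) == pytest.approx(math.log(0.64), abs=1e-10)

    def test_fallen_record(self):
        assert self._single(0, 0.8, 2.0) == pytest.approx(math.log(0.36), abs=1e-10)

    def test_additivity(self):
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=float(logit(0.8)), rho=np.array([0.0]), u=np.zeros(1),
            sigma_p=1.0, v=np.zeros(1), sigma_g=1.0, w=np.zeros(1),
            sigma_s=1.0, durability=make_tiny_model()[1].durability,
        )
        ds = SnagDataset.from_records(
            [
                _record({"AT": 0.0}, standing=1, interval_years=2.0),
                _record({"AT": 0.0}, standing=0, interval_years=2.0),
            ],
            spec,
        )
        assert log_likelihood(ds, params, spec) == pytest.approx(
            math.log(0.64) + math.log(0.36), abs=1e-10
        )

    def test_impossible_outcome_returns_sentinel(self):
        # enormous eta makes p**t numerically one; a fallen snag then has
        # probability zero and the sentinel, not an exception, comes back
        spec = CovariateSpec(("AT",), {"AT": 0.0}, {"AT": 1.0})
        params = ModelParameters(
            beta0=800.0, rho=np.array([0.0]), u=np.zeros(1), sigma_p=1.0,
            v=np.zeros(1), sigma_g=1.0, w=np.zeros(1), sigma_s=1.0,
            durability=make_tiny_model()[1].durability,
        )
        ds = SnagDataset.from_records(
            [_record({"AT": 0.0}, standing=0, interval_years=5.0)], spec
        )
        assert log_likelihood(ds, params, spec) == NEG_INF

    def test_matches_per_record_loop(self, rng):
        """Vectorized likelihood equals a naive scalar loop to 1e-10."""
        dataset, params, spec, grid, mask = make_tiny_model()
        for _ in range(20):
            n = int(rng.integers(1, 200))
            ds = SnagDataset(
                rng.integers(0, 2, size=n),
                rng.uniform(0.5, 8.0, size=n),
                rng.normal(10, 2, size=(n, 1)),
                rng.integers(0, 2, size=n),
                rng.integers(0, 4, size=n),
                rng.integers(0, 2, size=n),
                rng.integers(1, 6, size=n),
                spec,
            )
            total = 0.0
            for i in range(n):
                eta = (
                    params.beta0
                    + params.rho[0] * (ds.X[i, 0] - spec.centers["AT"])
                    + params.u[ds.phys_class[i]]
                    + params.v[ds.cell[i]]
                    + params.w[ds.species[i]]
                )
                p = 1.0 / (1.0 + math.exp(-eta))
                pt = p ** ds.interval_years[i]
                total += math.log(pt) if ds.standing[i] == 1 else math.log(1 - pt)
            assert log_likelihood(ds, params, spec) == pytest.approx(
                total, abs=1e-10
            )


class TestCarConditional:
    def test_mean_and_variance_from_two_neighbors(self):
        grid = SpatialGrid(3, [{1, 2}, {0}, {0}])
        v = np.array([0.0, 2.0, 4.0])
        mean, var = car_conditional(v, 0, grid, sigma_g=1.0)
        assert mean == pytest.approx(3.0)
        assert var == pytest.approx(0.5)

    def test_single_neighbor(self):
        grid = SpatialGrid(2, [{1}, {0}])
        mean, var = car_conditional(np.array([0.0, 5.0]), 0, grid, sigma_g=2.0)
        assert mean == pytest.approx(5.0)
        assert var == pytest.approx(4.0)

    def test_symmetric_neighbors_average_to_zero(self):
        grid = SpatialGrid(3, [{1, 2}, {0}, {0}])
        mean, _ = car_conditional(np.array([9.0, 1.0, -1.0]), 0, grid, 0.7)
        assert mean == pytest.approx(0.0)

    def test_joint_density_maximized_at_conditional_mean(self):
        """The ICAR joint log-density, as a function of one coordinate with
        the rest held fixed, peaks at the conditional mean."""
        grid = SpatialGrid.rectangular(3, 3)
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, size=9)
        k = 4  # interior cell
        mean, _ = car_conditional(v, k, grid, sigma_g=0.8)
        grid_vals = np.linspace(mean - 2, mean + 2, 401)
        dens = []
        for val in grid_vals:
            vv = v.copy()
            vv[k] = val
            dens.append(icar_logpdf(vv, grid, 0.8))
        assert grid_vals[int(np.argmax(dens))] == pytest.approx(mean, abs=0.02)

    def test_isolated_cell_gets_marginal_prior(self):
        grid = SpatialGrid(3, [{1}, {0}, set()])
        mean, var = car_conditional(np.array([1.0, 2.0, 3.0]), 2, grid, 0.5)
        assert mean == 0.0
        assert var == pytest.approx(0.25)


class TestDurabilityTransforms:
    def test_species_mean_zero_at_average(self, tiny_model):
        d = tiny_model[1].durability
        assert species_mean(d.dur_bar, d) == pytest.approx(0.0)

    def test_species_mean_linear(self, tiny_model):
        d = tiny_model[1].durability.copy()
        d.beta_dur, d.dur_bar = 0.3, 1.0
        assert species_mean(3.0, d) == pytest.approx(0.6)
        d.beta_dur = 0.0
        assert species_mean(3.7, d) == pytest.approx(0.0)

    def test_durability_logit_midpoint(self):
        assert durability_logit(2.0) == pytest.approx(0.0, abs=1e-12)

    def test_durability_logit_quarter(self):
        assert durability_logit(1.0) == pytest.approx(math.log(1 / 3), abs=1e-10)

    def test_durability_logit_boundary_finite_and_ordered(self):
        low = durability_logit(0.0)
        assert np.isfinite(low) and low < durability_logit(1.0)
        assert durability_logit(4.0) > durability_logit(3.0)

    def test_strict_monotonicity(self):
        xs = np.linspace(0, 4, 33)
        ys = durability_logit(xs)
        assert np.all(np.diff(ys) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            durability_logit(4.5)


class TestLogPrior:
    def test_sigma_outside_uniform_support(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        bad = params.copy()
        bad.sigma_s = 150.0
        assert log_prior(bad, grid, mask) == NEG_INF

    def test_matches_term_by_term_oracle(self, tiny_model):
        """Independent recomputation of every named density term."""
        dataset, params, spec, grid, mask = tiny_model
        d = params.durability
        diffuse_sd = math.sqrt(1000.0)
        tau_g = params.sigma_g**-2

        expected = 0.0
        # physiographic effects: iid normals
        for uj in params.u:
            expected += norm.logpdf(uj, 0, params.sigma_p)
        # intrinsic CAR in pairwise form; 2x2 rook grid has 4 edges, rank 3
        ss = 0.0
        for k, h in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            ss += (params.v[k] - params.v[h]) ** 2
        expected += 0.5 * 3 * math.log(tau_g) - 0.5 * tau_g * ss
        # Gamma(0.5, rate 2) on the precision, as a density over sigma
        expected += gamma_dist.logpdf(tau_g, a=0.5, scale=0.5)
        expected += math.log(2.0) - 3.0 * math.log(params.sigma_g)
        # species effects around durability-driven means
        for l, wl in enumerate(params.w):
            mu_l = d.beta_dur * (d.dur_imputed[l] - d.dur_bar)
            expected += norm.logpdf(wl, mu_l, params.sigma_s)
        # taxonomy on logit-durability (both species in scope by default)
        for l in range(2):
            z = logit(np.clip(d.dur_imputed[l], 0.05, 3.95) / 4.0)
            expected += norm.logpdf(z, d.mu_family[d.family_of_species[l]],
                                    d.sigma_family)
        for f in range(2):
            expected += norm.logpdf(
                d.mu_family[f], d.mu_division[d.division_of_family[f]],
                d.sigma_division,
            )
        # diffuse fixed effects; flat intercept contributes nothing
        expected += norm.logpdf(params.rho[0], 0, diffuse_sd)
        expected += norm.logpdf(d.beta_dur, 0, diffuse_sd)
        for mu in d.mu_division:
            expected += norm.logpdf(mu, 0, diffuse_sd)
        # Uniform(0,100) normalizers for sigma_p, sigma_s, sigma_f, sigma_d
        expected += 4 * math.log(1 / 100)

        assert log_prior(params, grid, mask) == pytest.approx(expected, abs=1e-10)

    def test_latent_only_scope_drops_observed_terms(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        full = log_prior(params, grid, mask, dur_prior_on_observed=True)
        latent = log_prior(params, grid, mask, dur_prior_on_observed=False)
        d = params.durability
        z0 = durability_logit(d.dur_imputed[0])
        dropped = norm.logpdf(z0, d.mu_family[0], d.sigma_family)
        assert full - latent == pytest.approx(dropped, abs=1e-10)


class TestLogPosterior:
    def test_additivity(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        assert log_posterior(dataset, params, spec, grid, mask) == pytest.approx(
            log_likelihood(dataset, params, spec) + log_prior(params, grid, mask),
            abs=1e-10,
        )

    def test_neg_inf_propagates(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        bad = params.copy()
        bad.sigma_p = -1.0
        assert log_posterior(dataset, bad, spec, grid, mask) == NEG_INF


class TestConstraints:
    def test_sum_to_zero_application(self, tiny_model):
        dataset, params, spec, grid, mask = tiny_model
        shifted = params.copy()
        shifted.u = shifted.u + 0.7
        shifted.w = shifted.w - 0.3
        out = shifted.apply_sum_to_zero()
        for vec in (out.u, out.v, out.w):
            assert abs(vec.sum()) < 1e-10
        # the linear predictor is invariant
        assert linear_predictor(dataset, out, spec) == pytest.approx(
            linear_predictor(dataset, shifted, spec), abs=1e-10
        )


class TestSpatialGrid:
    def test_rook_neighbor_counts(self):
        grid = SpatialGrid.rectangular(3, 4)
        counts = grid.neighbor_counts.reshape(3, 4)
        assert counts[0, 0] == 2 and counts[0, 1] == 3 and counts[1, 1] == 4

    def test_adjacency_symmetric_irreflexive(self):
        grid = SpatialGrid.rectangular(4, 4)
        a = grid.adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)
        assert np.array_equal(a.sum(axis=1), grid.neighbor_counts)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SpatialGrid(2, [{1}, set()])
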