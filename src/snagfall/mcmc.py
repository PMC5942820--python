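"""Posterior sampling for the snag persistence model.

Adaptive random-walk Metropolis-within-Gibbs over parameter blocks:

* intercept and covariate effects (full-likelihood scalar updates);
* physiographic, spatial and species effects (per-element updates that touch
  only the records in the corresponding group, via cached per-record
  likelihood terms);
* hierarchical standard deviations on the log scale;
* the durability sub-hierarchy (effect, family and division means, their
  spreads, and the latent logit-durabilities of species with no observed
  estimate), none of which touches the likelihood.

The spatial block is recentred to sum to zero after every sweep (the
intrinsic CAR prior is shift-invariant, and the flat-prior intercept absorbs
the shift, so the move is measure-preserving).  The exchangeable blocks are
left free in-chain and the sum-to-zero reparameterization is applied when a
draw is recorded, so every recorded state satisfies the constraints exactly.

Proposal scales adapt toward a 44% acceptance rate during burn-in only, so
the post-burn-in kernel is fixed and draws are reproducible from the seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import sparse
from scipy.stats import f as f_dist

from .durability import DurabilityTable
from .model import (
    NEG_INF,
    CovariateSpec,
    DurabilityModelParams,
    ModelParameters,
    SnagDataset,
    SpatialGrid,
    _gamma_precision_log_prior,
    durability_logit,
    icar_logpdf,
    log_posterior,
    species_mean,
)

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "BgrResult",
    "run_chains",
    "bgr_diagnostic",
    "fit_by_decay_class",
]

_SIGMA_MAX = 100.0
_DIFFUSE_SD = math.sqrt(1000.0)


@dataclass(frozen=True)
class ChainConfig:
    """Multi-chain sampling protocol.

    Desk-scale defaults (3 chains x 20,000 iterations, burn-in 2,000,
    thin 10) keep simulation studies tractable; the full field protocol
    (5 chains x 110,000, burn-in 10,000, thin 40, BGR threshold 1.05) is a
    matter of configuration.
    """

    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seeds: tuple[int, ...] | None = None
    bgr_threshold: float = 1.05
    adapt_interval: int = 50
    target_accept: float = 0.44
    dur_prior_on_observed: bool = True
    likelihood_off: bool = False
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.n_chains:
            raise ValueError("need exactly one seed per chain")

    def chain_seeds(self) -> tuple[int, ...]:
        if self.seeds is not None:
            return tuple(self.seeds)
        return tuple(self.base_seed + 1000 * c + 1 for c in range(self.n_chains))


class PosteriorDraws:
    """Thinned post-burn-in draws, indexed (chain, draw, parameter)."""

    def __init__(
        self,
        names: Sequence[str],
        values: np.ndarray,
        provenance: Mapping | None = None,
    ):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError(
                "values must have shape (n_chains, n_draws, n_params)"
            )
        self.provenance = dict(provenance or {})
        self._index = {nm: i for i, nm in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_draws)."""
        return self.values[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def names_matching(self, prefix: str) -> list[str]:
        return [nm for nm in self.names if nm.startswith(prefix)]

    def posterior_mean(self) -> dict[str, float]:
        means = self.values.reshape(-1, len(self.names)).mean(axis=0)
        return dict(zip(self.names, means))

    def summary(self, name: str) -> dict[str, float]:
        x = self.flat(name)
        lo, hi = np.quantile(x, [0.025, 0.975])
        return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)),
                "q2.5": float(lo), "q97.5": float(hi)}

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table."""
        c, d, p = self.values.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d * p),
                "draw": np.tile(np.repeat(np.arange(d), p), c),
                "parameter": np.tile(self.names, c * d),
                "value": self.values.reshape(-1),
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, provenance: Mapping | None = None
    ) -> "PosteriorDraws":
        names = list(dict.fromkeys(df["parameter"]))
        chains = sorted(df["chain"].unique())
        draws = sorted(df["draw"].unique())
        wide = df.pivot_table(
            index=["chain", "draw"], columns="parameter", values="value",
            sort=False,
        )[names]
        values = wide.to_numpy().reshape(len(chains), len(draws), len(names))
        return cls(names, values, provenance)

    def save(self, csv_path, manifest_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def load(cls, csv_path, manifest_path=None) -> "PosteriorDraws":
        prov = {}
        if manifest_path is not None:
            with open(manifest_path) as fh:
                prov = json.load(fh)
        return cls.from_dataframe(pd.read_csv(csv_path), prov)


def dataset_hash(dataset: SnagDataset) -> str:
    h = hashlib.sha256()
    for arr in (
        dataset.standing,
        dataset.interval_years,
        dataset.X,
        dataset.phys_class,
        dataset.cell,
        dataset.species,
        dataset.decay_class,
    ):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _norm_lp(x, mu, sigma):
    return -np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2  # constant dropped


def _loglik_terms(eta, S, t):
    """Per-record log-likelihood without the errstate guard (hot path)."""
    log_p = -np.logaddexp(0.0, -eta)
    t_log_p = t * log_p
    log_1mpt = np.log(-np.expm1(t_log_p))
    return np.where(S == 1, t_log_p, log_1mpt)


class _ScalarScale:
    """Scalar log proposal scale nudged toward a target acceptance rate."""

    def __init__(self, init: float = 0.5):
        self.log_scale = math.log(init)
        self.accepted = 0
        self.tried = 0

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)

    def record(self, accepted: bool) -> None:
        self.tried += 1
        self.accepted += accepted

    def adapt(self, target: float) -> None:
        if self.tried == 0:
            return
        self.log_scale += self.accepted / self.tried - target
        self.log_scale = min(max(self.log_scale, -8.0), 5.0)
        self.accepted = 0
        self.tried = 0

    def rate(self) -> float:
        return self.accepted / self.tried if self.tried else float("nan")


class _VectorScale:
    """Per-element log proposal scales for a simultaneous block update."""

    def __init__(self, size: int, init: float = 0.3):
        self.log_scale = np.full(size, math.log(init))
        self.accepted = np.zeros(size)
        self.tried = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def record(self, accepted: np.ndarray) -> None:
        self.tried += 1
        self.accepted += accepted

    def adapt(self, target: float) -> None:
        if self.tried == 0:
            return
        self.log_scale += self.accepted / self.tried - target
        np.clip(self.log_scale, -8.0, 5.0, out=self.log_scale)
        self.accepted[:] = 0.0
        self.tried = 0

    def rate(self) -> float:
        return float(np.mean(self.accepted) / self.tried) if self.tried else float("nan")


def _graph_coloring(grid: SpatialGrid) -> list[np.ndarray]:
    """Greedy coloring into independent sets (2 colors on rook lattices).

    Cells in one color class have no edges among themselves, so their CAR
    full conditionals are mutually independent and the class can be updated
    simultaneously.
    """
    colors = np.full(grid.n_cells, -1)
    for k in range(grid.n_cells):
        used = {colors[h] for h in grid.neighbor_sets[k] if colors[h] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[k] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]


class _ChainState:
    """Mutable state of one chain with cached eta and likelihood terms.

    Block updates are simultaneous Metropolis moves over conditionally
    independent elements; the likelihood change of every element is read off
    one vectorized pass with ``bincount``.
    """

    def __init__(
        self,
        dataset: SnagDataset,
        grid: SpatialGrid,
        spec: CovariateSpec,
        table: DurabilityTable,
        config: ChainConfig,
        rng: np.random.Generator,
    ):
        self.ds = dataset
        self.grid = grid
        self.spec = spec
        self.config = config
        self.rng = rng

        self.Xc = dataset.X - spec.center_vector()
        self.n = len(dataset)
        self.S = dataset.standing
        self.t = dataset.interval_years

        fam_of_sp, div_of_fam, self.families, self.divisions = (
            table.taxonomy_indices()
        )
        self.fam_of_sp = fam_of_sp
        self.div_of_fam = div_of_fam
        self.obs_mask = table.observed_mask
        if not self.obs_mask.any():
            raise ValueError("at least one species needs an observed durability")
        self.missing = np.flatnonzero(~self.obs_mask)
        self.species_names = table.species
        dur_bar = table.dur_bar()
        q = len(table.species)
        m = int(dataset.phys_class.max()) + 1
        p = grid.n_cells
        self.sizes = {"u": m, "v": p, "w": q}

        # adjacency as CSR for neighbor sums; color classes for v updates
        n_edges = len(grid.edges)
        rows = np.concatenate([grid.edges[:, 0], grid.edges[:, 1]]) if n_edges else np.array([], dtype=int)
        cols = np.concatenate([grid.edges[:, 1], grid.edges[:, 0]]) if n_edges else np.array([], dtype=int)
        self.A = sparse.csr_matrix(
            (np.ones(2 * n_edges), (rows, cols)), shape=(p, p)
        )
        self.deg = grid.neighbor_counts.astype(float)
        self.v_colors = _graph_coloring(grid)
        self.isolated_mask = np.zeros(p, dtype=bool)
        self.isolated_mask[grid.isolated] = True

        # taxonomy scope for the durability measurement model
        self.z_scope = (
            np.ones(q, dtype=bool)
            if config.dur_prior_on_observed
            else ~self.obs_mask
        )
        self.fam_sizes_scope = np.bincount(
            fam_of_sp[self.z_scope], minlength=len(self.families)
        ).astype(float)
        self.div_fam_sizes = np.bincount(
            div_of_fam, minlength=len(self.divisions)
        ).astype(float)

        # initialization: empirical baseline, zero effects, unit spreads
        frac_standing = float(np.clip(self.S.mean(), 0.02, 0.98))
        p_annual0 = frac_standing ** (1.0 / float(self.t.mean()))
        beta0 = float(logit(p_annual0))
        dur_init = np.where(self.obs_mask, table.durability, np.nan)
        mu_f0 = np.empty(len(self.families))
        for f in range(len(self.families)):
            obs = dur_init[fam_of_sp == f]
            obs = obs[~np.isnan(obs)]
            mu_f0[f] = durability_logit(float(obs.mean())) if obs.size else 0.0
        dur_full = dur_init.copy()
        for l in self.missing:
            dur_full[l] = 4.0 * expit(mu_f0[fam_of_sp[l]])

        jitter = lambda s: float(rng.normal(0.0, s))
        self.params = ModelParameters(
            beta0=beta0 + jitter(0.1),
            rho=rng.normal(0.0, 0.02, size=len(spec.names)),
            u=np.zeros(m),
            sigma_p=math.exp(jitter(0.1)),
            v=np.zeros(p),
            sigma_g=math.exp(jitter(0.1)),
            w=np.zeros(q),
            sigma_s=math.exp(jitter(0.1)),
            durability=DurabilityModelParams(
                beta_dur=jitter(0.05),
                dur_bar=dur_bar,
                mu_family=mu_f0 + rng.normal(0.0, 0.05, size=len(mu_f0)),
                sigma_family=1.0,
                mu_division=np.zeros(len(self.divisions)),
                sigma_division=1.0,
                dur_imputed=dur_full,
                family_of_species=fam_of_sp,
                division_of_family=div_of_fam,
            ),
        )
        self.z = durability_logit(self.params.durability.dur_imputed)

        self.eta = self._full_eta()
        self.terms = _loglik_terms(self.eta, self.S, self.t)
        if not np.all(np.isfinite(self.terms)):
            raise RuntimeError("non-finite likelihood at initialization")

        # proposal scales
        self.scalar_scales = {
            "beta0": _ScalarScale(0.05),
            "sigma_p": _ScalarScale(0.3),
            "sigma_g": _ScalarScale(0.3),
            "sigma_s": _ScalarScale(0.3),
            "sigma_f": _ScalarScale(0.3),
            "sigma_d": _ScalarScale(0.3),
            "beta_dur": _ScalarScale(0.1),
        }
        for nm in spec.names:
            self.scalar_scales[f"rho[{nm}]"] = _ScalarScale(0.05)
        self.vector_scales = {
            "u": _VectorScale(m, 0.2),
            "v": _VectorScale(p, 0.2),
            "w": _VectorScale(q, 0.2),
            "z": _VectorScale(len(self.missing), 0.4),
            "mu_f": _VectorScale(len(self.families), 0.3),
            "mu_d": _VectorScale(len(self.divisions), 0.3),
        }

    # -- helpers ------------------------------------------------------------

    def _full_eta(self) -> np.ndarray:
        prm = self.params
        return (
            prm.beta0
            + self.Xc @ prm.rho
            + prm.u[self.ds.phys_class]
            + prm.v[self.ds.cell]
            + prm.w[self.ds.species]
        )

    def refresh_cache(self) -> None:
        """Recompute eta/terms from scratch (guards against float drift)."""
        self.eta = self._full_eta()
        self.terms = _loglik_terms(self.eta, self.S, self.t)

    def _accept_scalar(self, log_ratio: float) -> bool:
        if not np.isfinite(log_ratio):
            return False if log_ratio < 0 or np.isnan(log_ratio) else True
        return math.log(self.rng.uniform()) < log_ratio

    # -- scalar likelihood updates ------------------------------------------

    def _scalar_likelihood_update(self, name, current, delta_eta_unit):
        """RW update of a scalar whose change shifts eta by delta * unit."""
        sc = self.scalar_scales[name]
        delta = self.rng.normal(0.0, sc.scale)
        if self.config.likelihood_off:
            d_ll, new_terms = 0.0, None
        else:
            new_terms = _loglik_terms(
                self.eta + delta * delta_eta_unit, self.S, self.t
            )
            d_ll = float(new_terms.sum() - self.terms.sum())
            if not np.isfinite(d_ll):
                d_ll = NEG_INF
        return sc, delta, d_ll, new_terms

    def update_beta0(self) -> None:
        sc, delta, d_ll, new_terms = self._scalar_likelihood_update(
            "beta0", self.params.beta0, 1.0
        )
        ok = self._accept_scalar(d_ll)  # flat prior
        if ok:
            self.params.beta0 += delta
            self.eta += delta
            if new_terms is not None:
                self.terms = new_terms
        sc.record(ok)

    def update_rho(self) -> None:
        for j, nm in enumerate(self.spec.names):
            unit = self.Xc[:, j]
            sc, delta, d_ll, new_terms = self._scalar_likelihood_update(
                f"rho[{nm}]", self.params.rho[j], unit
            )
            new_val = self.params.rho[j] + delta
            d_prior = float(
                _norm_lp(new_val, 0, _DIFFUSE_SD)
                - _norm_lp(self.params.rho[j], 0, _DIFFUSE_SD)
            )
            ok = self._accept_scalar(d_ll + d_prior)
            if ok:
                self.params.rho[j] = new_val
                self.eta += delta * unit
                if new_terms is not None:
                    self.terms = new_terms
            sc.record(ok)

    # -- simultaneous block updates ------------------------------------------

    def _block_likelihood_delta(self, gid, delta, size):
        """Per-element likelihood change when element g shifts eta by delta[g].

        Returns (d_ll per element, proposed per-record terms).
        """
        if self.config.likelihood_off:
            return np.zeros(size), None
        new_terms = _loglik_terms(self.eta + delta[gid], self.S, self.t)
        diff = new_terms - self.terms
        bad = ~np.isfinite(new_terms)
        if bad.any():
            diff = np.where(bad, NEG_INF, diff)
        d_ll = np.bincount(gid, weights=diff, minlength=size)
        return d_ll, new_terms

    def _apply_block(self, vec, gid, delta, accept, new_terms) -> None:
        acc_delta = np.where(accept, delta, 0.0)
        vec += acc_delta
        if new_terms is not None and accept.any():
            rec_acc = accept[gid]
            shift = acc_delta[gid]
            self.eta += shift
            self.terms = np.where(rec_acc, new_terms, self.terms)

    def _simultaneous_update(self, name, vec, gid, prior_delta_fn) -> None:
        vs = self.vector_scales[name]
        delta = self.rng.standard_normal(len(vec)) * vs.scale
        d_ll, new_terms = self._block_likelihood_delta(gid, delta, len(vec))
        log_r = d_ll + prior_delta_fn(vec, delta)
        log_r = np.where(np.isnan(log_r), NEG_INF, log_r)
        accept = np.log(self.rng.uniform(size=len(vec))) < log_r
        self._apply_block(vec, gid, delta, accept, new_terms)
        vs.record(accept)

    def update_u(self) -> None:
        sp = self.params.sigma_p

        def prior_delta(vec, delta):
            return _norm_lp(vec + delta, 0.0, sp) - _norm_lp(vec, 0.0, sp)

        self._simultaneous_update("u", self.params.u, self.ds.phys_class, prior_delta)

    def update_w(self) -> None:
        d = self.params.durability
        mu_l = species_mean(d.dur_imputed, d)
        ss = self.params.sigma_s

        def prior_delta(vec, delta):
            return _norm_lp(vec + delta, mu_l, ss) - _norm_lp(vec, mu_l, ss)

        self._simultaneous_update("w", self.params.w, self.ds.species, prior_delta)

    def update_v(self) -> None:
        """Color-class-wise simultaneous update of the CAR field.

        Within one color class no two cells are adjacent, so the pairwise
        prior change of each cell involves only out-of-class values and the
        simultaneous move is a valid product of independent Metropolis steps.
        Afterwards the field is recentred (the intrinsic prior is
        shift-invariant; the flat-prior intercept absorbs the mean).
        """
        prm = self.params
        v = prm.v
        tau = prm.sigma_g**-2
        vs = self.vector_scales["v"]
        scale = vs.scale
        gid = self.ds.cell
        accept_all = np.zeros(len(v), dtype=bool)
        for cls in self.v_colors:
            delta_full = np.zeros(len(v))
            delta_full[cls] = self.rng.standard_normal(len(cls)) * scale[cls]
            d_ll, new_terms = self._block_likelihood_delta(
                gid, delta_full, len(v)
            )
            nbr_sum = self.A @ v
            dp = -0.5 * tau * (
                self.deg * delta_full**2
                + 2.0 * delta_full * (self.deg * v - nbr_sum)
            )
            iso = self.isolated_mask
            if iso.any():
                dp[iso] = _norm_lp(v[iso] + delta_full[iso], 0.0, prm.sigma_g) - _norm_lp(
                    v[iso], 0.0, prm.sigma_g
                )
            log_r = d_ll + dp
            log_r = np.where(np.isnan(log_r), NEG_INF, log_r)
            accept = np.log(self.rng.uniform(size=len(v))) < log_r
            # restrict acceptance to the proposed class
            mask = np.zeros(len(v), dtype=bool)
            mask[cls] = True
            accept &= mask
            self._apply_block(v, gid, delta_full, accept, new_terms)
            accept_all |= accept
        vs.record(accept_all)
        m = float(v.mean())
        v -= m
        self.params.beta0 += m

    def update_z(self) -> None:
        """Latent logit-durabilities of unobserved species (no likelihood)."""
        if len(self.missing) == 0:
            return
        prm = self.params
        d = prm.durability
        vs = self.vector_scales["z"]
        z_old = self.z[self.missing]
        delta = self.rng.standard_normal(len(self.missing)) * vs.scale
        z_new = z_old + delta
        dur_old = d.dur_imputed[self.missing]
        dur_new = 4.0 * expit(z_new)
        mu_f_l = d.mu_family[self.fam_of_sp[self.missing]]
        w_l = prm.w[self.missing]
        log_r = (
            _norm_lp(z_new, mu_f_l, d.sigma_family)
            - _norm_lp(z_old, mu_f_l, d.sigma_family)
            + _norm_lp(w_l, d.beta_dur * (dur_new - d.dur_bar), prm.sigma_s)
            - _norm_lp(w_l, d.beta_dur * (dur_old - d.dur_bar), prm.sigma_s)
        )
        accept = np.log(self.rng.uniform(size=len(self.missing))) < log_r
        self.z[self.missing] = np.where(accept, z_new, z_old)
        d.dur_imputed[self.missing] = np.where(accept, dur_new, dur_old)
        vs.record(accept)

    def update_taxonomy_means(self) -> None:
        """Family and division means of logit-durability (no likelihood)."""
        d = self.params.durability
        n_fam = len(self.families)

        # family means: normal terms over in-scope member z's + division prior
        vs = self.vector_scales["mu_f"]
        delta = self.rng.standard_normal(n_fam) * vs.scale
        z_sum = np.bincount(
            self.fam_of_sp[self.z_scope],
            weights=self.z[self.z_scope],
            minlength=n_fam,
        )
        n_f = self.fam_sizes_scope
        old = d.mu_family
        new = old + delta
        inv2sf = 0.5 / d.sigma_family**2
        d_members = -inv2sf * (n_f * (new**2 - old**2) - 2.0 * delta * z_sum)
        mu_d_f = d.mu_division[self.div_of_fam]
        d_div = _norm_lp(new, mu_d_f, d.sigma_division) - _norm_lp(
            old, mu_d_f, d.sigma_division
        )
        accept = np.log(self.rng.uniform(size=n_fam)) < d_members + d_div
        d.mu_family = np.where(accept, new, old)
        vs.record(accept)

        # division means: normal terms over member families + diffuse prior
        vs = self.vector_scales["mu_d"]
        n_div = len(self.divisions)
        delta = self.rng.standard_normal(n_div) * vs.scale
        f_sum = np.bincount(
            self.div_of_fam, weights=d.mu_family, minlength=n_div
        )
        old = d.mu_division
        new = old + delta
        inv2sd = 0.5 / d.sigma_division**2
        d_fams = -inv2sd * (
            self.div_fam_sizes * (new**2 - old**2) - 2.0 * delta * f_sum
        )
        d_diffuse = _norm_lp(new, 0.0, _DIFFUSE_SD) - _norm_lp(old, 0.0, _DIFFUSE_SD)
        accept = np.log(self.rng.uniform(size=n_div)) < d_fams + d_diffuse
        d.mu_division = np.where(accept, new, old)
        vs.record(accept)

    def update_beta_dur(self) -> None:
        prm = self.params
        d = prm.durability
        sc = self.scalar_scales["beta_dur"]
        delta = self.rng.normal(0.0, sc.scale)
        new = d.beta_dur + delta
        centered = d.dur_imputed - d.dur_bar
        lr = float(
            np.sum(_norm_lp(prm.w, new * centered, prm.sigma_s))
            - np.sum(_norm_lp(prm.w, d.beta_dur * centered, prm.sigma_s))
            + _norm_lp(new, 0, _DIFFUSE_SD)
            - _norm_lp(d.beta_dur, 0, _DIFFUSE_SD)
        )
        ok = self._accept_scalar(lr)
        if ok:
            d.beta_dur = new
        sc.record(ok)

    # -- scale (sigma) updates -----------------------------------------------

    def _update_log_sigma(self, name: str, logdens) -> None:
        sc = self.scalar_scales[name]
        old = self._sigma_get(name)
        s_new = math.log(old) + self.rng.normal(0.0, sc.scale)
        new = math.exp(s_new)
        lr = logdens(new) - logdens(old) + (s_new - math.log(old))
        ok = self._accept_scalar(lr)
        if ok:
            self._sigma_set(name, new)
        sc.record(ok)

    def _sigma_get(self, name: str) -> float:
        if name == "sigma_f":
            return self.params.durability.sigma_family
        if name == "sigma_d":
            return self.params.durability.sigma_division
        return getattr(self.params, name)

    def _sigma_set(self, name: str, value: float) -> None:
        if name == "sigma_f":
            self.params.durability.sigma_family = value
        elif name == "sigma_d":
            self.params.durability.sigma_division = value
        else:
            setattr(self.params, name, value)

    def update_sigmas(self) -> None:
        prm = self.params
        d = prm.durability

        def lp_sigma_p(s):
            if not 0 < s < _SIGMA_MAX:
                return NEG_INF
            return float(np.sum(_norm_lp(prm.u, 0, s)))

        def lp_sigma_s(s):
            if not 0 < s < _SIGMA_MAX:
                return NEG_INF
            mu_l = species_mean(d.dur_imputed, d)
            return float(np.sum(_norm_lp(prm.w, mu_l, s)))

        def lp_sigma_g(s):
            return icar_logpdf(prm.v, self.grid, s) + _gamma_precision_log_prior(s)

        def lp_sigma_f(s):
            if not 0 < s < _SIGMA_MAX:
                return NEG_INF
            mu = d.mu_family[self.fam_of_sp]
            sc = self.z_scope
            return float(np.sum(_norm_lp(self.z[sc], mu[sc], s)))

        def lp_sigma_d(s):
            if not 0 < s < _SIGMA_MAX:
                return NEG_INF
            mu = d.mu_division[self.div_of_fam]
            return float(np.sum(_norm_lp(d.mu_family, mu, s)))

        for name, fn in [
            ("sigma_p", lp_sigma_p),
            ("sigma_g", lp_sigma_g),
            ("sigma_s", lp_sigma_s),
            ("sigma_f", lp_sigma_f),
            ("sigma_d", lp_sigma_d),
        ]:
            self._update_log_sigma(name, fn)

    # -- sweep / adaptation ---------------------------------------------------

    def sweep(self) -> None:
        self.update_beta0()
        self.update_rho()
        self.update_u()
        self.update_v()
        self.update_w()
        self.update_sigmas()
        self.update_beta_dur()
        self.update_z()
        self.update_taxonomy_means()

    def adapt(self) -> None:
        for sc in self.scalar_scales.values():
            sc.adapt(self.config.target_accept)
        for vs in self.vector_scales.values():
            vs.adapt(self.config.target_accept)

    # -- recording ------------------------------------------------------------

    def record_names(self) -> list[str]:
        names = ["beta0"]
        names += [f"rho[{nm}]" for nm in self.spec.names]
        names += ["sigma_p", "sigma_g", "sigma_s", "sigma_f", "sigma_d", "beta_dur"]
        names += [f"mu_d[{dv}]" for dv in self.divisions]
        names += [f"mu_f[{fam}]" for fam in self.families]
        names += [f"u[{j}]" for j in range(len(self.params.u))]
        names += [f"v[{k}]" for k in range(len(self.params.v))]
        names += [f"w[{l}]" for l in range(len(self.params.w))]
        names += [f"dur[{self.species_names[l]}]" for l in self.missing]
        return names

    def record(self) -> np.ndarray:
        prm = self.params.apply_sum_to_zero()
        d = prm.durability
        out = [prm.beta0]
        out += list(prm.rho)
        out += [prm.sigma_p, prm.sigma_g, prm.sigma_s, d.sigma_family,
                d.sigma_division, d.beta_dur]
        out += list(d.mu_division)
        out += list(d.mu_family)
        out += list(prm.u)
        out += list(prm.v)
        out += list(prm.w)
        out += list(d.dur_imputed[self.missing])
        return np.array(out)

    def acceptance_rates(self) -> dict[str, float]:
        rates = {nm: sc.rate() for nm, sc in self.scalar_scales.items()}
        rates.update({nm: vs.rate() for nm, vs in self.vector_scales.items()})
        return rates


def run_chains(
    dataset: SnagDataset,
    grid: SpatialGrid,
    spec: CovariateSpec,
    chain_config: ChainConfig,
    durability_table: DurabilityTable,
) -> PosteriorDraws:
    """Sample the joint posterior with the configured multi-chain protocol.

    Latent durabilities of unobserved species are sampled jointly with the
    rest.  Returns thinned post-burn-in draws; the per-block acceptance rates
    and a low-acceptance flag are attached to the provenance.
    """
    cfg = chain_config
    seeds = cfg.chain_seeds()
    all_chains = []
    names: list[str] | None = None
    reports = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        state = _ChainState(dataset, grid, spec, durability_table, cfg, rng)
        if names is None:
            names = state.record_names()
        kept = []
        # log(0) -> -inf is the intended sentinel for impossible outcomes
        with np.errstate(divide="ignore", invalid="ignore"):
            for it in range(cfg.n_iterations):
                state.sweep()
                if (it + 1) % 2000 == 0:
                    state.refresh_cache()
                if it < cfg.burn_in:
                    if (it + 1) % cfg.adapt_interval == 0:
                        state.adapt()
                    if it == cfg.burn_in - 1:
                        # freeze scales; reset counters for the report
                        for sc in state.scalar_scales.values():
                            sc.accepted = sc.tried = 0
                        for vs in state.vector_scales.values():
                            vs.accepted[:] = 0.0
                            vs.tried = 0
                elif (it - cfg.burn_in + 1) % cfg.thin == 0:
                    kept.append(state.record())
        rates = state.acceptance_rates()
        finite = [r for r in rates.values() if np.isfinite(r)]
        reports.append(
            {
                "seed": seed,
                "min_acceptance": float(min(finite)) if finite else float("nan"),
                "stalled_blocks": [
                    nm for nm, r in rates.items() if np.isfinite(r) and r < 0.01
                ],
            }
        )
        all_chains.append(np.asarray(kept))

    values = np.stack(all_chains)
    provenance = {
        "config": {
            "n_chains": cfg.n_chains,
            "n_iterations": cfg.n_iterations,
            "burn_in": cfg.burn_in,
            "thin": cfg.thin,
            "bgr_threshold": cfg.bgr_threshold,
            "dur_prior_on_observed": cfg.dur_prior_on_observed,
            "likelihood_off": cfg.likelihood_off,
        },
        "seeds": list(seeds),
        "dataset_hash": dataset_hash(dataset),
        "chain_reports": reports,
        "covariates": list(spec.names),
        "centers": dict(spec.centers),
        "sds": dict(spec.sds),
    }
    return PosteriorDraws(names, values, provenance)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BgrResult:
    """Brooks-Gelman-Rubin potential scale reduction factor per parameter."""

    point: Mapping[str, float]
    upper: Mapping[str, float]
    threshold: float

    @property
    def converged(self) -> bool:
        finite = [x for x in self.upper.values() if np.isfinite(x)]
        return bool(finite) and max(finite) < self.threshold

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.point),
                "psrf": list(self.point.values()),
                "psrf_upper": [self.upper[k] for k in self.point],
            }
        )


def _bgr_single(x: np.ndarray) -> tuple[float, float]:
    """Corrected scale-reduction factor and its 97.5% upper limit.

    ``x`` has shape (n_chains, n_draws).  Follows the Brooks & Gelman (1998)
    sampling-variance construction: the pooled-posterior variance estimate is
    compared to the within-chain variance, with a t-distribution degrees-of-
    freedom correction and an F-quantile on the between-chain ratio for the
    upper limit.
    """
    m, n = x.shape
    if m < 2 or n < 10:
        raise ValueError("BGR needs >= 2 chains and >= 10 draws per chain")
    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = float(s2.mean())
    B = float(n * xbar.var(ddof=1))
    if W == 0.0:
        return 1.0, 1.0
    muhat = float(x.mean())
    var_w = float(s2.var(ddof=1)) / m
    var_b = 2.0 * B**2 / (m - 1)
    cov_wb = (n / m) * (
        float(np.cov(s2, xbar**2, ddof=1)[0, 1])
        - 2.0 * muhat * float(np.cov(s2, xbar, ddof=1)[0, 1])
    )
    sig2hat = (n - 1) * W / n + B / n
    V = sig2hat + B / (m * n)
    var_V = (
        ((n - 1) ** 2) * var_w + ((1 + 1 / m) ** 2) * var_b
        + 2 * (n - 1) * (1 + 1 / m) * cov_wb
    ) / n**2
    df_adj = 1.0
    if var_V > 0:
        df_V = 2 * V**2 / var_V
        df_adj = (df_V + 3) / (df_V + 1)
    B_df = m - 1
    W_df = 2 * W**2 / var_w if var_w > 0 else np.inf
    R2_fixed = (n - 1) / n
    R2_random = (1 + 1 / m) * (1 / n) * (B / W)
    point = math.sqrt(df_adj * (R2_fixed + R2_random))
    if np.isfinite(W_df):
        q = float(f_dist.ppf(0.975, B_df, W_df))
    else:
        from scipy.stats import chi2

        q = float(chi2.ppf(0.975, B_df)) / B_df
    upper = math.sqrt(df_adj * (R2_fixed + q * R2_random))
    return point, upper


def bgr_diagnostic(
    draws: PosteriorDraws,
    parameters: Sequence[str] | None = None,
    threshold: float | None = None,
) -> BgrResult:
    """BGR statistic with 97.5% upper limit for each requested parameter."""
    if draws.n_chains < 2:
        raise ValueError("BGR diagnostic requires at least two chains")
    params = list(parameters) if parameters is not None else list(draws.names)
    thr = threshold
    if thr is None:
        thr = draws.provenance.get("config", {}).get("bgr_threshold", 1.05)
    point, upper = {}, {}
    for nm in params:
        pt, up = _bgr_single(draws.get(nm))
        point[nm], upper[nm] = pt, up
    return BgrResult(point, upper, float(thr))


def fit_by_decay_class(
    dataset: SnagDataset,
    grid: SpatialGrid,
    spec: CovariateSpec,
    chain_config: ChainConfig,
    durability_table: DurabilityTable,
) -> dict[int, PosteriorDraws]:
    """Independent refits on each decay-class subset.

    Covariate centers and sds are recomputed per subset; empty classes are
    skipped.  Keys are the decay classes present in the data.
    """
    out: dict[int, PosteriorDraws] = {}
    for dc in sorted(np.unique(dataset.decay_class)):
        sub = dataset.subset(dataset.decay_class == dc)
        sub_spec = CovariateSpec(
            spec.names,
            centers={
                nm: float(sub.X[:, j].mean()) for j, nm in enumerate(spec.names)
            },
            sds={
                nm: float(sub.X[:, j].std(ddof=1)) for j, nm in enumerate(spec.names)
            },
        )
        sub = SnagDataset(
            sub.standing, sub.interval_years, sub.X, sub.phys_class, sub.cell,
            sub.species, sub.decay_class, sub_spec,
        )
        out[int(dc)] = run_chains(sub, grid, sub_spec, chain_config, durability_table)
    return out
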