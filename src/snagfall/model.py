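"""Hierarchical interval-censored persistence model for standing dead trees.

A snag observed standing at one inventory visit either remains standing at the
resurvey ``t`` years later or has fallen in between.  The outcome is a single
Bernoulli trial with success probability ``p**t``, where ``p`` is the
*annualized* probability of remaining standing.  ``logit(p)`` is a linear
function of centered continuous covariates plus exchangeable physiographic
effects, spatially structured grid-cell effects (intrinsic Gaussian CAR), and
species effects whose means depend linearly on ordinal wood durability
(0 = least durable, 4 = most durable).  Durability itself carries a taxonomic
hierarchy (species within family within division) on the logit(DUR/4) scale,
which supports imputation of species with no published durability estimate.

Everything here is a deterministic function of a parameter state; sampling
lives in :mod:`snagfall.mcmc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "SnagRecord",
    "SnagDataset",
    "CovariateSpec",
    "SpatialGrid",
    "DurabilityModelParams",
    "ModelParameters",
    "DEFAULT_COVARIATES",
    "ALL_COVARIATES",
    "linear_predictor",
    "annual_persistence",
    "standing_probability",
    "log_likelihood",
    "car_conditional",
    "species_mean",
    "durability_logit",
    "log_prior",
    "log_posterior",
]

NEG_INF = float("-inf")

#: covariates of the simplified model (temperature, diameter, stand density);
#: wood durability enters through the species hierarchy, not this list.
DEFAULT_COVARIATES = ("AT", "DIA", "TPH")
#: every covariate the data model accepts.
ALL_COVARIATES = ("AT", "WND", "SL", "QMD", "TPH", "DIA", "DEN")

# diffuse normal prior variance for fixed effects (precision 0.001)
_DIFFUSE_VAR = 1000.0
# upper bound of the uniform prior on hierarchical standard deviations
_SIGMA_MAX = 100.0
# clamp for the ordinal durability scale before logit(DUR/4)
DUR_CLAMP = 0.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnagRecord:
    """One interval-censored observation of a standing dead tree.

    Indices are 0-based internally (files use 1-based, see snagfall.io).
    """

    standing: int
    interval_years: float
    covariates: Mapping[str, float]
    phys_class: int
    cell: int
    species: int
    decay_class: int = 1

    def __post_init__(self) -> None:
        if self.standing not in (0, 1):
            raise ValueError(f"standing must be 0 or 1, got {self.standing}")
        if not self.interval_years > 0:
            raise ValueError(f"interval_years must be > 0, got {self.interval_years}")
        if self.decay_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"decay_class must be in 1..5, got {self.decay_class}")


@dataclass(frozen=True)
class CovariateSpec:
    """Active continuous covariates with their centering constants.

    ``centers`` are subtracted before applying the coefficients so the
    intercept is the annualized baseline log-odds of standing at average
    covariate conditions; ``sds`` support standardized effect sizes.
    """

    names: tuple[str, ...]
    centers: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        for nm in self.names:
            if nm not in self.centers or nm not in self.sds:
                raise ValueError(f"centers/sds missing entry for covariate {nm!r}")
            if not self.sds[nm] > 0:
                raise ValueError(f"sd for covariate {nm!r} must be > 0")

    @classmethod
    def from_data(cls, names: Sequence[str], table) -> "CovariateSpec":
        """Compute centers/sds from a DataFrame-like with covariate columns."""
        centers = {nm: float(np.mean(table[nm])) for nm in names}
        sds = {}
        for nm in names:
            sd = float(np.std(table[nm], ddof=1))
            # degenerate (constant or single-row) columns fall back to unit sd
            sds[nm] = sd if np.isfinite(sd) and sd > 0 else 1.0
        return cls(tuple(names), centers, sds)

    def center_vector(self) -> np.ndarray:
        return np.array([self.centers[nm] for nm in self.names], dtype=float)

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sds[nm] for nm in self.names], dtype=float)


class SpatialGrid:
    """Rectangular cell lattice (or arbitrary graph) for the CAR prior.

    Parameters
    ----------
    n_cells:
        Number of cells ``p``.
    neighbor_sets:
        Per-cell sets of adjacent cell indices (0-based).  Must be symmetric
        and irreflexive.
    cell_bounds:
        Optional per-cell (lat_min, lat_max, lon_min, lon_max) rectangles,
        closed on the lower/left edge, used to assign plots to cells.
    """

    def __init__(
        self,
        n_cells: int,
        neighbor_sets: Sequence[Iterable[int]],
        cell_bounds: Sequence[tuple[float, float, float, float]] | None = None,
    ):
        if len(neighbor_sets) != n_cells:
            raise ValueError("neighbor_sets length must equal n_cells")
        self.n_cells = int(n_cells)
        self.neighbor_sets = [frozenset(int(h) for h in s) for s in neighbor_sets]
        for k, s in enumerate(self.neighbor_sets):
            if k in s:
                raise ValueError(f"cell {k} listed as its own neighbor")
            for h in s:
                if not 0 <= h < n_cells:
                    raise ValueError(f"neighbor index {h} out of range")
                if k not in self.neighbor_sets[h]:
                    raise ValueError(f"adjacency not symmetric between {k} and {h}")
        self.neighbor_counts = np.array([len(s) for s in self.neighbor_sets])
        self.cell_bounds = cell_bounds
        # edge list with k < h, each unordered pair once
        self.edges = np.array(
            sorted(
                (k, h)
                for k, s in enumerate(self.neighbor_sets)
                for h in s
                if k < h
            ),
            dtype=int,
        ).reshape(-1, 2)
        self.isolated = np.flatnonzero(self.neighbor_counts == 0)

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix ``a_kh``."""
        a = np.zeros((self.n_cells, self.n_cells), dtype=int)
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1
            a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a

    def n_components(self) -> int:
        """Number of connected components among non-isolated cells."""
        seen = set(self.isolated.tolist())
        n_comp = 0
        for start in range(self.n_cells):
            if start in seen:
                continue
            n_comp += 1
            stack = [start]
            seen.add(start)
            while stack:
                k = stack.pop()
                for h in self.neighbor_sets[k]:
                    if h not in seen:
                        seen.add(h)
                        stack.append(h)
        return n_comp

    @classmethod
    def rectangular(cls, n_rows: int, n_cols: int) -> "SpatialGrid":
        """Rook-adjacency lattice; cell index = row * n_cols + col."""
        p = n_rows * n_cols
        sets: list[set[int]] = [set() for _ in range(p)]
        for r in range(n_rows):
            for c in range(n_cols):
                k = r * n_cols + c
                if r > 0:
                    sets[k].add(k - n_cols)
                if r < n_rows - 1:
                    sets[k].add(k + n_cols)
                if c > 0:
                    sets[k].add(k - 1)
                if c < n_cols - 1:
                    sets[k].add(k + 1)
        return cls(p, sets)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpatialGrid)
            and self.n_cells == other.n_cells
            and self.neighbor_sets == other.neighbor_sets
        )


@dataclass
class DurabilityModelParams:
    """Durability submodel state: effect, taxonomy means, imputed values.

    ``dur_imputed`` holds a value for every species on the 0-4 ordinal scale;
    entries where the observation mask is True are fixed data, the rest are
    latent and sampled.  ``family_of_species`` / ``division_of_family`` encode
    the taxonomy as 0-based index arrays.
    """

    beta_dur: float
    dur_bar: float
    mu_family: np.ndarray
    sigma_family: float
    mu_division: np.ndarray
    sigma_division: float
    dur_imputed: np.ndarray
    family_of_species: np.ndarray
    division_of_family: np.ndarray

    def __post_init__(self) -> None:
        self.mu_family = np.asarray(self.mu_family, dtype=float)
        self.mu_division = np.asarray(self.mu_division, dtype=float)
        self.dur_imputed = np.asarray(self.dur_imputed, dtype=float)
        self.family_of_species = np.asarray(self.family_of_species, dtype=int)
        self.division_of_family = np.asarray(self.division_of_family, dtype=int)
        if np.any(self.dur_imputed < 0) or np.any(self.dur_imputed > 4):
            raise ValueError("durability values must lie in [0, 4]")

    def copy(self) -> "DurabilityModelParams":
        return DurabilityModelParams(
            self.beta_dur,
            self.dur_bar,
            self.mu_family.copy(),
            self.sigma_family,
            self.mu_division.copy(),
            self.sigma_division,
            self.dur_imputed.copy(),
            self.family_of_species,
            self.division_of_family,
        )


@dataclass
class ModelParameters:
    """Complete unknown state of the persistence model."""

    beta0: float
    rho: np.ndarray
    u: np.ndarray
    sigma_p: float
    v: np.ndarray
    sigma_g: float
    w: np.ndarray
    sigma_s: float
    durability: DurabilityModelParams

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.beta0,
            self.rho.copy(),
            self.u.copy(),
            self.sigma_p,
            self.v.copy(),
            self.sigma_g,
            self.w.copy(),
            self.sigma_s,
            self.durability.copy(),
        )

    def apply_sum_to_zero(self) -> "ModelParameters":
        """Recenter u, v, w to sum to zero, folding the means into beta0.

        The linear predictor (hence the likelihood) is invariant under this
        transformation because the intercept absorbs the shift.
        """
        out = self.copy()
        for name in ("u", "v", "w"):
            vec = getattr(out, name)
            m = float(vec.mean()) if vec.size else 0.0
            setattr(out, name, vec - m)
            out.beta0 += m
        return out


class SnagDataset:
    """Column-oriented container for a set of snag observations.

    Holds numpy arrays aligned with a :class:`CovariateSpec`; the covariate
    matrix ``X`` is stored uncentered (centering happens at evaluation).
    """

    def __init__(
        self,
        standing: np.ndarray,
        interval_years: np.ndarray,
        X: np.ndarray,
        phys_class: np.ndarray,
        cell: np.ndarray,
        species: np.ndarray,
        decay_class: np.ndarray,
        spec: CovariateSpec,
    ):
        self.standing = np.asarray(standing, dtype=int)
        self.interval_years = np.asarray(interval_years, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.phys_class = np.asarray(phys_class, dtype=int)
        self.cell = np.asarray(cell, dtype=int)
        self.species = np.asarray(species, dtype=int)
        self.decay_class = np.asarray(decay_class, dtype=int)
        self.spec = spec
        n = len(self.standing)
        for arr, nm in [
            (self.interval_years, "interval_years"),
            (self.phys_class, "phys_class"),
            (self.cell, "cell"),
            (self.species, "species"),
            (self.decay_class, "decay_class"),
        ]:
            if len(arr) != n:
                raise ValueError(f"column {nm} has length {len(arr)}, expected {n}")
        if self.X.shape != (n, len(spec.names)):
            raise ValueError(
                f"covariate matrix shape {self.X.shape} does not match "
                f"({n}, {len(spec.names)})"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariate matrix contains non-finite values")
        if np.any(self.interval_years <= 0):
            raise ValueError("interval_years must be strictly positive")
        if not np.isin(self.standing, (0, 1)).all():
            raise ValueError("standing must be 0/1")

    def __len__(self) -> int:
        return len(self.standing)

    @classmethod
    def from_records(
        cls, records: Sequence[SnagRecord], spec: CovariateSpec
    ) -> "SnagDataset":
        if not records:
            raise ValueError("dataset must contain at least one record")
        X = np.empty((len(records), len(spec.names)))
        for i, r in enumerate(records):
            for j, nm in enumerate(spec.names):
                if nm not in r.covariates:
                    raise ValueError(f"record {i} missing covariate {nm!r}")
                X[i, j] = r.covariates[nm]
        return cls(
            np.array([r.standing for r in records]),
            np.array([r.interval_years for r in records]),
            X,
            np.array([r.phys_class for r in records]),
            np.array([r.cell for r in records]),
            np.array([r.species for r in records]),
            np.array([r.decay_class for r in records]),
            spec,
        )

    def subset(self, mask: np.ndarray) -> "SnagDataset":
        mask = np.asarray(mask)
        return SnagDataset(
            self.standing[mask],
            self.interval_years[mask],
            self.X[mask],
            self.phys_class[mask],
            self.cell[mask],
            self.species[mask],
            self.decay_class[mask],
            self.spec,
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "standing": self.standing,
                "interval_years": self.interval_years,
                "decay_class": self.decay_class,
                "phys_class": self.phys_class,
                "cell": self.cell,
                "species": self.species,
            }
        )
        for j, nm in enumerate(self.spec.names):
            df[nm] = self.X[:, j]
        return df


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_dataset(data, spec: CovariateSpec):
    """Accept a SnagRecord or a SnagDataset; return column views."""
    if isinstance(data, SnagRecord):
        ds = SnagDataset.from_records([data], spec)
        return ds, True
    return data, False


def _check_indices(ds: SnagDataset, params: ModelParameters) -> None:
    for arr, vec, nm in [
        (ds.phys_class, params.u, "phys_class"),
        (ds.cell, params.v, "cell"),
        (ds.species, params.w, "species"),
    ]:
        if arr.size and (arr.min() < 0 or arr.max() >= len(vec)):
            raise ValueError(
                f"{nm} index out of range: max {arr.max()} for {len(vec)} levels"
            )


# ---------------------------------------------------------------------------
# likelihood-side operations
# ---------------------------------------------------------------------------


def linear_predictor(data, params: ModelParameters, spec: CovariateSpec):
    """Logit-scale annual persistence: intercept + covariates + u + v + w.

    ``data`` may be a single :class:`SnagRecord` (returns a float) or a
    :class:`SnagDataset` (returns an array).
    """
    ds, scalar = _as_dataset(data, spec)
    if tuple(ds.spec.names) != tuple(spec.names):
        raise ValueError("dataset covariate order does not match spec")
    if len(params.rho) != len(spec.names):
        raise ValueError(
            f"rho has length {len(params.rho)}, spec has {len(spec.names)} covariates"
        )
    _check_indices(ds, params)
    eta = (
        params.beta0
        + (ds.X - spec.center_vector()) @ params.rho
        + params.u[ds.phys_class]
        + params.v[ds.cell]
        + params.w[ds.species]
    )
    return float(eta[0]) if scalar else eta


def annual_persistence(data, params: ModelParameters, spec: CovariateSpec):
    """Annualized probability of remaining standing (inverse-logit of eta)."""
    return expit(linear_predictor(data, params, spec))


def standing_probability(p, t):
    """Probability of standing over an interval of ``t`` years: ``p**t``."""
    p_arr = np.asarray(p, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("annual persistence p must lie strictly in (0, 1)")
    if np.any(t_arr <= 0):
        raise ValueError("interval t must be strictly positive")
    out = p_arr**t_arr
    return float(out) if np.isscalar(p) and np.isscalar(t) else out


def _loglik_from_eta(
    eta: np.ndarray, standing: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Per-record log-likelihood terms given the linear predictor.

    S * t * log(p) + (1 - S) * log(1 - p**t), computed in log space so that
    p**t near 0 or 1 degrades to -inf rather than raising.
    """
    log_p = -np.logaddexp(0.0, -eta)  # log expit(eta)
    t_log_p = t * log_p
    with np.errstate(divide="ignore"):
        # log(1 - p**t) = log(-expm1(t log p)); exact 0 -> -inf
        log_1mpt = np.log(-np.expm1(t_log_p))
    return np.where(standing == 1, t_log_p, log_1mpt)


def log_likelihood(dataset: SnagDataset, params: ModelParameters, spec: CovariateSpec):
    """Joint Bernoulli log-likelihood over all records.

    Returns ``-inf`` (a sentinel, never an exception) when any record has an
    outcome of probability numerically zero, so samplers can reject.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    eta = linear_predictor(dataset, params, spec)
    terms = _loglik_from_eta(eta, dataset.standing, dataset.interval_years)
    total = float(np.sum(terms))
    return total if np.isfinite(total) else NEG_INF


def car_conditional(
    v: np.ndarray, k: int, grid: SpatialGrid, sigma_g: float
) -> tuple[float, float]:
    """Full conditional of one cell under the intrinsic CAR: (mean, variance).

    Mean is the average of the neighbors' effects; variance is
    ``sigma_g**2 / a_k+``.  An isolated cell gets an independent
    Normal(0, sigma_g**2), matching the joint prior below.
    """
    if not sigma_g > 0:
        raise ValueError("sigma_g must be > 0")
    nbrs = sorted(grid.neighbor_sets[k])
    if not nbrs:
        return 0.0, float(sigma_g**2)
    vals = np.asarray(v, dtype=float)[nbrs]
    return float(vals.mean()), float(sigma_g**2 / len(nbrs))


# ---------------------------------------------------------------------------
# durability submodel
# ---------------------------------------------------------------------------


def species_mean(dur_l: float, durability_params: DurabilityModelParams):
    """Expected species effect: beta_DUR * (DUR_l - mean observed DUR)."""
    dur = np.asarray(dur_l, dtype=float)
    if np.any(dur < 0) or np.any(dur > 4):
        raise ValueError("durability must lie in [0, 4]")
    out = durability_params.beta_dur * (dur - durability_params.dur_bar)
    return float(out) if np.isscalar(dur_l) else out


def durability_logit(dur):
    """Map ordinal durability in [0,4] to the real line via logit(DUR/4).

    The scale endpoints are clamped to [0.05, 3.95] first so categories 0 and
    4 map to finite values while preserving strict ordering.
    """
    arr = np.asarray(dur, dtype=float)
    if np.any(arr < 0) or np.any(arr > 4):
        raise ValueError("durability must lie in [0, 4]")
    clamped = np.clip(arr, DUR_CLAMP, 4.0 - DUR_CLAMP)
    out = logit(clamped / 4.0)
    return float(out) if np.isscalar(dur) else out


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def _norm_logpdf(x, mu, sigma):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def icar_logpdf(v: np.ndarray, grid: SpatialGrid, sigma_g: float) -> float:
    """Improper intrinsic-CAR log-density of the spatial field (pairwise form).

    ``(rank/2) log tau - (tau/2) * sum_edges (v_k - v_h)^2`` with
    ``tau = sigma_g**-2`` and rank = (#non-isolated cells) - (#components);
    the constant pseudo-determinant of the structure matrix is omitted.
    Isolated cells contribute independent Normal(0, sigma_g**2) terms.
    """
    if not sigma_g > 0:
        return NEG_INF
    v = np.asarray(v, dtype=float)
    tau = sigma_g**-2
    n_nonisolated = grid.n_cells - len(grid.isolated)
    rank = n_nonisolated - grid.n_components()
    ss = 0.0
    if len(grid.edges):
        diffs = v[grid.edges[:, 0]] - v[grid.edges[:, 1]]
        ss = float(np.sum(diffs**2))
    lp = 0.5 * rank * np.log(tau) - 0.5 * tau * ss
    if len(grid.isolated):
        lp += float(np.sum(_norm_logpdf(v[grid.isolated], 0.0, sigma_g)))
    return float(lp)


def _gamma_precision_log_prior(sigma: float, shape: float = 0.5, rate: float = 2.0):
    """Gamma(shape, rate) prior on the precision, as a density over sigma.

    Includes the Jacobian |d tau / d sigma| = 2 sigma**-3 so the value is a
    proper log-density with respect to sigma itself.
    """
    if not 0 < sigma < _SIGMA_MAX:
        return NEG_INF
    tau = sigma**-2.0
    log_gamma = (
        shape * math.log(rate) - math.lgamma(shape) + (shape - 1) * math.log(tau) - rate * tau
    )
    return log_gamma + math.log(2.0) - 3.0 * math.log(sigma)


def log_prior(
    params: ModelParameters,
    grid: SpatialGrid,
    observed_dur_mask: np.ndarray,
    dur_prior_on_observed: bool = True,
) -> float:
    """Joint log-prior over all model unknowns.

    Terms: exchangeable normals on physiographic effects, the intrinsic CAR
    on spatial effects with a Gamma(0.5, 2) prior on its precision,
    durability-centered normals on species effects, the taxonomic hierarchy
    on logit-durability (over all species by default, or latent-only when
    ``dur_prior_on_observed`` is False), diffuse Normal(0, 1000) on each
    fixed effect, a flat prior on the intercept, and Uniform(0, 100) on the
    hierarchical standard deviations.  Returns ``-inf`` as a sentinel for any
    out-of-support state.
    """
    d = params.durability
    for sigma in (params.sigma_p, params.sigma_s, d.sigma_family, d.sigma_division):
        if not 0 < sigma < _SIGMA_MAX:
            return NEG_INF
    if not 0 < params.sigma_g < _SIGMA_MAX:
        return NEG_INF
    observed_dur_mask = np.asarray(observed_dur_mask, dtype=bool)

    lp = 0.0
    # physiographic effects
    lp += float(np.sum(_norm_logpdf(params.u, 0.0, params.sigma_p)))
    # spatial field + precision prior
    lp += icar_logpdf(params.v, grid, params.sigma_g)
    lp += _gamma_precision_log_prior(params.sigma_g)
    # species effects around durability-driven means
    mu_l = species_mean(d.dur_imputed, d)
    lp += float(np.sum(_norm_logpdf(params.w, mu_l, params.sigma_s)))
    # taxonomy on logit-durability
    z = durability_logit(d.dur_imputed)
    mu_f_per_species = d.mu_family[d.family_of_species]
    if dur_prior_on_observed:
        lp += float(np.sum(_norm_logpdf(z, mu_f_per_species, d.sigma_family)))
    else:
        m = ~observed_dur_mask
        lp += float(
            np.sum(_norm_logpdf(z[m], mu_f_per_species[m], d.sigma_family))
        )
    # family means within divisions
    mu_d_per_family = d.mu_division[d.division_of_family]
    lp += float(np.sum(_norm_logpdf(d.mu_family, mu_d_per_family, d.sigma_division)))
    # diffuse fixed-effect priors; flat on beta0
    diffuse_sd = math.sqrt(_DIFFUSE_VAR)
    lp += float(np.sum(_norm_logpdf(params.rho, 0.0, diffuse_sd)))
    lp += float(_norm_logpdf(d.beta_dur, 0.0, diffuse_sd))
    lp += float(np.sum(_norm_logpdf(d.mu_division, 0.0, diffuse_sd)))
    # Uniform(0,100) normalizers for the four uniform sigmas
    lp += 4 * (-math.log(_SIGMA_MAX))
    return lp if np.isfinite(lp) else NEG_INF


def log_posterior(
    dataset: SnagDataset,
    params: ModelParameters,
    spec: CovariateSpec,
    grid: SpatialGrid,
    observed_dur_mask: np.ndarray,
    dur_prior_on_observed: bool = True,
) -> float:
    """Unnormalized log-posterior; ``-inf`` propagates from either term."""
    lp = log_prior(params, grid, observed_dur_mask, dur_prior_on_observed)
    if lp == NEG_INF:
        return NEG_INF
    ll = log_likelihood(dataset, params, spec)
    if ll == NEG_INF:
        return NEG_INF
    return ll + lp
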