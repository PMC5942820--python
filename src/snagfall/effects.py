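"""Posterior effect interpretation: standardized effects, average predictive
comparisons, and half-lives.

An average predictive comparison (APC) perturbs one predictor by a fixed,
biologically meaningful amount ``xi`` for *every* observed snag, holding all
other predictors at their observed values, and averages the change in the
predicted response over the dataset.  Repeating the computation for each
posterior draw turns parameter (and durability-imputation) uncertainty into
an interval on the response scale: the annualized probability of remaining
standing, or — for snags in the earliest decay class — the expected
half-life in years (``log 0.5 / log p``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .durability import DurabilityTable
from .mcmc import PosteriorDraws
from .model import CovariateSpec, SnagDataset, SpatialGrid

__all__ = [
    "PredictiveComparison",
    "EffectSummary",
    "half_life",
    "standardized_effect",
    "average_predictive_comparison",
    "average_with_imputation",
    "default_scenarios",
]

RESPONSES = ("annual_prob", "half_life", "linear")


@dataclass
class PredictiveComparison:
    """Per-draw APC values with their posterior summary."""

    focal: str
    xi: float
    response: str
    deltas: np.ndarray
    mean: float
    ci: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "focal": self.focal,
                "xi": self.xi,
                "response": self.response,
                "draw": np.arange(len(self.deltas)),
                "delta": self.deltas,
            }
        )


@dataclass(frozen=True)
class EffectSummary:
    covariate: str
    standardized_mean: float
    standardized_ci: tuple[float, float]
    raw_mean: float
    raw_ci: tuple[float, float]
    sd_used: float
    convention: str  # "divide" (as reported) or "multiply"


def half_life(p):
    """Years until standing probability reaches one half: log(0.5)/log(p)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("annual persistence p must lie strictly in (0, 1)")
    out = np.log(0.5) / np.log(arr)
    return float(out) if np.isscalar(p) else out


def standardized_effect(
    draws: PosteriorDraws,
    covariate: str,
    spec: CovariateSpec,
    durability_table: DurabilityTable | None = None,
    convention: str = "divide",
) -> EffectSummary:
    """Effect size standardized by the covariate's data standard deviation.

    The reported convention divides the posterior mean and 95% CI limits by
    the sd; the conventional multiply-by-sd alternative (effect of a one-sd
    change) is available as ``convention="multiply"``.  For
    ``covariate="durability"`` the sd of the durability data depends on the
    imputed values, so it is recomputed from each draw's imputation and the
    summary is averaged over draws.
    """
    if convention not in ("divide", "multiply"):
        raise ValueError("convention must be 'divide' or 'multiply'")

    if covariate == "durability":
        if durability_table is None:
            raise ValueError("durability_table required for the durability effect")
        raw = draws.flat("beta_dur")
        dur = np.repeat(
            durability_table.durability[None, :], len(raw), axis=0
        )
        missing_names = [
            nm for nm in draws.names_matching("dur[")
        ]
        if missing_names:
            idx = [durability_table.species.index(nm[4:-1]) for nm in missing_names]
            imputed = np.column_stack([draws.flat(nm) for nm in missing_names])
            dur[:, idx] = imputed
        sds = dur.std(axis=1, ddof=1)
        if np.any(sds <= 0):
            raise ValueError("zero durability sd")
        std_draws = raw / sds if convention == "divide" else raw * sds
        sd_used = float(sds.mean())
    else:
        if covariate not in spec.names:
            raise ValueError(f"covariate {covariate!r} not in spec")
        sd = spec.sds[covariate]
        if not sd > 0:
            raise ValueError("zero covariate sd")
        raw = draws.flat(f"rho[{covariate}]")
        std_draws = raw / sd if convention == "divide" else raw * sd
        sd_used = float(sd)

    lo_r, hi_r = np.quantile(raw, [0.025, 0.975])
    lo_s, hi_s = np.quantile(std_draws, [0.025, 0.975])
    return EffectSummary(
        covariate,
        float(std_draws.mean()),
        (float(lo_s), float(hi_s)),
        float(raw.mean()),
        (float(lo_r), float(hi_r)),
        sd_used,
        convention,
    )


def _draw_matrix(draws: PosteriorDraws, names: Sequence[str]) -> np.ndarray:
    """Flattened (n_total_draws, len(names)) matrix of draws."""
    return np.column_stack([draws.flat(nm) for nm in names])


def _eta_components(
    dataset: SnagDataset,
    draws: PosteriorDraws,
    spec: CovariateSpec,
    take: np.ndarray,
):
    """Linear predictors of the selected draws for every record.

    Returns an array of shape (len(take), n_records).
    """
    Xc = dataset.X - spec.center_vector()
    beta0 = draws.flat("beta0")[take][:, None]
    rho = _draw_matrix(draws, [f"rho[{nm}]" for nm in spec.names])[take]
    u = _draw_matrix(draws, draws.names_matching("u["))[take]
    v = _draw_matrix(draws, draws.names_matching("v["))[take]
    w = _draw_matrix(draws, draws.names_matching("w["))[take]
    return (
        beta0
        + rho @ Xc.T
        + u[:, dataset.phys_class]
        + v[:, dataset.cell]
        + w[:, dataset.species]
    )


def _response(eta: np.ndarray, response: str) -> np.ndarray:
    if response == "linear":
        return eta
    p = expit(eta)
    if response == "annual_prob":
        return p
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("half-life undefined for p at 0 or 1")
    return np.log(0.5) / np.log(p)


def _apc_core(
    dataset: SnagDataset,
    draws: PosteriorDraws,
    spec: CovariateSpec,
    focal: str,
    xi: float,
    response: str,
    n_posterior_draws: int,
    seed: int,
    durability_override: np.ndarray | None,
    durability_table: DurabilityTable | None,
) -> PredictiveComparison:
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    if not np.isfinite(xi):
        raise ValueError("xi must be finite")
    if response == "half_life":
        keep = dataset.decay_class == 1
        if not keep.any():
            raise ValueError("no earliest-decay-class records for half-life APC")
        dataset = dataset.subset(keep)

    rng = np.random.default_rng(seed)
    total = draws.n_chains * draws.n_draws
    if n_posterior_draws == total:
        take = np.arange(total)
    else:
        take = rng.choice(
            total, size=n_posterior_draws, replace=total < n_posterior_draws
        )

    if focal != "durability" and focal not in spec.names:
        raise ValueError(f"unknown focal predictor {focal!r}")

    # chunk over draws to bound the (draws x records) working set
    deltas = np.empty(len(take))
    chunk = max(1, int(2e7) // max(len(dataset), 1))
    for start in range(0, len(take), chunk):
        sel = take[start : start + chunk]
        eta = _eta_components(dataset, draws, spec, sel)
        if focal == "durability":
            beta_dur = draws.flat("beta_dur")[sel][:, None]
            if durability_override is not None:
                # shift the fitted eta from the draw's own imputation to the
                # supplied (plug-in) durability values before perturbing
                if durability_table is None:
                    raise ValueError("durability_table required for plug-in APC")
                dur_fixed = durability_override[dataset.species][None, :]
                dur_draw = np.repeat(
                    durability_table.durability[None, :], len(sel), axis=0
                )
                miss = draws.names_matching("dur[")
                if miss:
                    idx = [
                        durability_table.species.index(nm[4:-1]) for nm in miss
                    ]
                    dur_draw[:, idx] = np.column_stack(
                        [draws.flat(nm)[sel] for nm in miss]
                    )
                dur_draw = dur_draw[:, dataset.species]
                eta = eta + beta_dur * (dur_fixed - dur_draw)
            eta_pert = eta + beta_dur * xi
        else:
            rho_focal = draws.flat(f"rho[{focal}]")[sel][:, None]
            eta_pert = eta + rho_focal * xi
        deltas[start : start + chunk] = (
            _response(eta_pert, response) - _response(eta, response)
        ).mean(axis=1)
    lo, hi = np.quantile(deltas, [0.025, 0.975])
    return PredictiveComparison(
        focal, float(xi), response, deltas, float(deltas.mean()),
        (float(lo), float(hi)),
    )


def average_predictive_comparison(
    dataset: SnagDataset,
    draws: PosteriorDraws,
    spec: CovariateSpec,
    grid: SpatialGrid | None = None,
    focal: str = "AT",
    xi: float = 1.0,
    response: str = "annual_prob",
    n_posterior_draws: int = 5000,
    seed: int = 0,
    durability_table: DurabilityTable | None = None,
) -> PredictiveComparison:
    """APC of a covariate (or durability, plug-in imputation) by ``xi``.

    For ``focal="durability"`` the prediction holds each species' durability
    at its single best (posterior-mean imputed) value; use
    :func:`average_with_imputation` to propagate imputation uncertainty.
    """
    override = None
    if focal == "durability":
        if durability_table is None:
            raise ValueError("durability_table required for the durability APC")
        override = _posterior_mean_durability(draws, durability_table)
    return _apc_core(
        dataset, draws, spec, focal, xi, response, n_posterior_draws, seed,
        override, durability_table,
    )


def _posterior_mean_durability(
    draws: PosteriorDraws, table: DurabilityTable
) -> np.ndarray:
    dur = table.durability.copy()
    for nm in draws.names_matching("dur["):
        dur[table.species.index(nm[4:-1])] = float(draws.flat(nm).mean())
    if np.any(np.isnan(dur)):
        raise ValueError("durability table has missing species not in the draws")
    return dur


def average_with_imputation(
    dataset: SnagDataset,
    draws: PosteriorDraws,
    spec: CovariateSpec,
    grid: SpatialGrid | None = None,
    xi: float = -1.0,
    response: str = "annual_prob",
    n_draws: int = 5000,
    seed: int = 0,
    durability_table: DurabilityTable | None = None,
) -> PredictiveComparison:
    """Durability APC with each draw's own imputed durabilities substituted.

    With no missing durabilities this reduces exactly to
    :func:`average_predictive_comparison`.
    """
    if durability_table is None:
        raise ValueError("durability_table required")
    return _apc_core(
        dataset, draws, spec, "durability", xi, response, n_draws, seed,
        None, durability_table,
    )


def default_scenarios() -> list[dict]:
    """Mid-century change scenarios for each important driver."""
    return [
        {"focal": "AT", "xi": 2.4, "units": "deg C"},
        {"focal": "DIA", "xi": 3.5, "units": "cm"},
        {"focal": "TPH", "xi": -100.0, "units": "trees/ha"},
        {"focal": "durability", "xi": -1.0, "units": "durability class"},
    ]
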