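"""Spatially implicit, discrete-time forest carbon model with a snag pool.

Four pools (kg C ha^-1): live biomass, litter, standing dead wood (snags),
and down dead wood (logs).  Each year live biomass gains a fixed NPP input
and loses mortality (split between snag-forming and direct-to-log mortality)
and litter production; snags fall to the log pool at rate ``f = 1 - p_snag``
where ``p_snag`` is the annual persistence probability of a snag; each
detritus pool loses a first-order decay fraction to heterotrophic
respiration.  The model is linear, so steady states solve in closed form and
the sensitivity of snag C and NEP to a change in snag persistence alone
(decay rates held fixed) is cheap to evaluate over posterior draws.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CarbonConfig",
    "CarbonPools",
    "SensitivityResult",
    "step",
    "simulate",
    "steady_state",
    "nep",
    "max_nep",
    "persistence_sensitivity",
    "load_config",
    "default_config",
]


@dataclass(frozen=True)
class CarbonConfig:
    """Annual rates of the carbon model (all per year, timestep = 1 yr).

    ``snag_fraction`` is the share of mortality that forms snags; the rest
    goes straight to the log pool (windthrown live stems).
    """

    npp: float  # kg C ha-1 yr-1 entering live biomass
    mortality_rate: float
    snag_fraction: float
    litter_rate: float
    k_litter: float
    k_snag: float
    k_log: float
    p_snag: float

    def __post_init__(self) -> None:
        if self.npp < 0:
            raise ValueError("npp must be non-negative")
        for nm in ("mortality_rate", "snag_fraction", "litter_rate",
                   "k_litter", "k_snag", "k_log"):
            val = getattr(self, nm)
            if not 0 <= val <= 1:
                raise ValueError(f"{nm} must lie in [0, 1], got {val}")
        if not 0 < self.p_snag < 1:
            raise ValueError("p_snag must lie strictly in (0, 1)")
        if self.mortality_rate + self.litter_rate > 1:
            raise ValueError("live-pool outflow exceeds the pool per step")
        if self.fall_rate + self.k_snag > 1:
            raise ValueError("snag-pool outflow exceeds the pool per step")

    @property
    def fall_rate(self) -> float:
        return 1.0 - self.p_snag

    def require_contracting(self) -> None:
        """Steady state needs every pool to have strictly positive outflow."""
        for nm, val in [
            ("live", self.mortality_rate + self.litter_rate),
            ("litter", self.k_litter),
            ("snag", self.fall_rate + self.k_snag),
            ("log", self.k_log),
        ]:
            if not val > 0:
                raise ValueError(f"{nm} pool has no outflow; no steady state")


@dataclass(frozen=True)
class CarbonPools:
    """Pool stocks (kg C ha^-1) plus cumulative heterotrophic loss."""

    live: float = 0.0
    litter: float = 0.0
    snag: float = 0.0
    log: float = 0.0
    het_loss: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("live", "litter", "snag", "log"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} stock must be non-negative")

    @property
    def total(self) -> float:
        return self.live + self.litter + self.snag + self.log


def step(state: CarbonPools, config: CarbonConfig) -> CarbonPools:
    """Advance the pools one year; exact input/output bookkeeping."""
    c = config
    mortality = c.mortality_rate * state.live
    litterfall = c.litter_rate * state.live
    to_snag = c.snag_fraction * mortality
    to_log_direct = mortality - to_snag
    fall = c.fall_rate * state.snag
    decay_litter = c.k_litter * state.litter
    decay_snag = c.k_snag * state.snag
    decay_log = c.k_log * state.log
    return CarbonPools(
        live=state.live + c.npp - mortality - litterfall,
        litter=state.litter + litterfall - decay_litter,
        snag=state.snag + to_snag - fall - decay_snag,
        log=state.log + fall + to_log_direct - decay_log,
        het_loss=state.het_loss + decay_litter + decay_snag + decay_log,
    )


def simulate(
    config: CarbonConfig, n_steps: int, init: CarbonPools | None = None
) -> pd.DataFrame:
    """Trajectory of pool stocks and annual NEP over ``n_steps`` years."""
    state = init if init is not None else CarbonPools()
    rows = []
    for year in range(n_steps + 1):
        rows.append(
            {
                "year": year,
                "live": state.live,
                "litter": state.litter,
                "snag": state.snag,
                "log": state.log,
                "het_loss": state.het_loss,
                "nep": nep(state, config),
            }
        )
        if year < n_steps:
            state = step(state, config)
    return pd.DataFrame(rows)


def steady_state(config: CarbonConfig) -> CarbonPools:
    """Closed-form fixed point of the linear transfer map."""
    c = config
    c.require_contracting()
    live = c.npp / (c.mortality_rate + c.litter_rate)
    mortality = c.mortality_rate * live
    to_snag = c.snag_fraction * mortality
    snag = to_snag / (c.fall_rate + c.k_snag)
    log = (c.fall_rate * snag + mortality - to_snag) / c.k_log
    litter = c.litter_rate * live / c.k_litter
    return CarbonPools(live=live, litter=litter, snag=snag, log=log)


def nep(state: CarbonPools, config: CarbonConfig) -> float:
    """Net ecosystem production: NPP minus heterotrophic decay flux.

    Positive = net uptake.  Zero at the steady state of this closed model;
    equals NPP when the detritus pools are empty.
    """
    c = config
    resp = c.k_litter * state.litter + c.k_snag * state.snag + c.k_log * state.log
    return c.npp - resp


def max_nep(config: CarbonConfig) -> float:
    """Upper bound of NEP over all states: the empty-detritus value (= NPP)."""
    return nep(CarbonPools(), config)


@dataclass
class SensitivityResult:
    """Change in steady-state snag C and horizon NEP from altered persistence."""

    baseline: CarbonPools
    baseline_nep: float
    scenario_snag: np.ndarray
    scenario_nep: np.ndarray
    horizon: int

    @property
    def delta_snag(self) -> np.ndarray:
        return self.scenario_snag - self.baseline.snag

    @property
    def delta_snag_pct(self) -> np.ndarray:
        return 100.0 * self.delta_snag / self.baseline.snag

    @property
    def delta_nep(self) -> np.ndarray:
        return self.scenario_nep - self.baseline_nep

    @property
    def delta_nep_pct(self) -> np.ndarray:
        return 100.0 * self.delta_nep / self.baseline_nep

    def summary(self) -> dict:
        def s(x):
            lo, hi = np.quantile(x, [0.025, 0.975])
            return {"mean": float(np.mean(x)), "q2.5": float(lo), "q97.5": float(hi)}

        return {
            "baseline_snag_c": self.baseline.snag,
            "baseline_nep": self.baseline_nep,
            "horizon_years": self.horizon,
            "delta_snag_c": s(self.delta_snag),
            "delta_snag_c_pct": s(self.delta_snag_pct),
            "delta_nep": s(self.delta_nep),
            "delta_nep_pct": s(self.delta_nep_pct),
        }


def _nep_at_horizon(config: CarbonConfig, horizon: int) -> float:
    """NEP after ``horizon`` years of detritus accumulation.

    Starts from live biomass at steady state and empty detritus pools, so the
    value reflects how quickly the detritus pathway (snags vs logs) returns C
    to the atmosphere; at the steady state of this closed model NEP is
    identically zero, which carries no sensitivity information.
    """
    live0 = config.npp / (config.mortality_rate + config.litter_rate)
    state = CarbonPools(live=live0)
    for _ in range(horizon):
        state = step(state, config)
    return nep(state, config)


def persistence_sensitivity(
    config: CarbonConfig,
    baseline_p: float,
    scenario_p_draws: Sequence[float],
    horizon: int = 50,
) -> SensitivityResult:
    """Effect of changed snag persistence on snag C and NEP.

    For each scenario draw only the fall rate ``f = 1 - p`` changes; decay
    rates are held fixed.  Snag C is compared at steady state; NEP is
    compared ``horizon`` years into detritus accumulation (see
    :func:`_nep_at_horizon`).
    """
    draws = np.asarray(scenario_p_draws, dtype=float)
    if np.any(draws <= 0) or np.any(draws >= 1) or not 0 < baseline_p < 1:
        raise ValueError("persistence probabilities must lie strictly in (0, 1)")
    base_cfg = replace(config, p_snag=float(baseline_p))
    baseline = steady_state(base_cfg)
    baseline_nep = _nep_at_horizon(base_cfg, horizon)
    snag = np.empty(len(draws))
    nep_h = np.empty(len(draws))
    for i, p in enumerate(draws):
        cfg = replace(config, p_snag=float(p))
        snag[i] = steady_state(cfg).snag
        nep_h[i] = _nep_at_horizon(cfg, horizon)
    return SensitivityResult(baseline, baseline_nep, snag, nep_h, horizon)


def load_config(path) -> CarbonConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = CarbonConfig.__dataclass_fields__.keys()
    extra = set(raw) - set(known)
    if extra:
        raise ValueError(f"unknown carbon config keys: {sorted(extra)}")
    return CarbonConfig(**raw)


def default_config() -> CarbonConfig:
    """The packaged northern-hardwood-like illustrative parameterization."""
    ref = importlib.resources.files("snagfall.configs") / "northern_hardwood.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_config(path)
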