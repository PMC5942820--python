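"""Model adequacy: rounded predictions, exact odds ratio, calibration tables.

Predictions are made at posterior-mean parameters: a record is predicted
standing when its interval survival probability ``p**t`` rounds to 1 (ties at
0.5 round to standing).  The association between observed and predicted
outcomes is summarized by the conditional maximum-likelihood odds ratio with
an exact central confidence interval from Fisher's noncentral hypergeometric
distribution — the same construction as R's ``fisher.test``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import fisher_exact, nchypergeom_fisher

from .model import (
    CovariateSpec,
    ModelParameters,
    SnagDataset,
    annual_persistence,
    standing_probability,
)

__all__ = [
    "ContingencyTable",
    "AdequacyReport",
    "predict_standing",
    "proportion_correct",
    "exact_odds_ratio",
    "observed_vs_expected",
    "adequacy_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = observed standing/fallen, cols = predicted."""

    obs_standing_pred_standing: int
    obs_standing_pred_fallen: int
    obs_fallen_pred_standing: int
    obs_fallen_pred_fallen: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.as_array().reshape(-1)):
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.obs_standing_pred_standing, self.obs_standing_pred_fallen],
                [self.obs_fallen_pred_standing, self.obs_fallen_pred_fallen],
            ],
            dtype=int,
        )

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


@dataclass
class AdequacyReport:
    proportion_correct: float
    table: ContingencyTable
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    p_value: float
    by_group: Mapping[str, pd.DataFrame]

    def to_dict(self) -> dict:
        return {
            "proportion_correct": self.proportion_correct,
            "table": self.table.as_array().tolist(),
            "odds_ratio": self.odds_ratio,
            "odds_ratio_ci": list(self.odds_ratio_ci),
            "p_value": self.p_value,
        }


def interval_survival(
    dataset: SnagDataset, params: ModelParameters, spec: CovariateSpec
) -> np.ndarray:
    """``p**t`` for every record at the given (point) parameters."""
    p = annual_persistence(dataset, params, spec)
    return standing_probability(p, dataset.interval_years)


def predict_standing(data, params_point: ModelParameters, spec: CovariateSpec):
    """Rounded expected outcome: 1 iff ``p**t >= 0.5``."""
    if isinstance(data, SnagDataset):
        return (interval_survival(data, params_point, spec) >= 0.5).astype(int)
    p = annual_persistence(data, params_point, spec)
    return int(standing_probability(p, data.interval_years) >= 0.5)


def proportion_correct(
    dataset: SnagDataset, params_point: ModelParameters, spec: CovariateSpec
) -> tuple[float, ContingencyTable]:
    """Fraction of records whose rounded prediction matches the outcome."""
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    pred = predict_standing(dataset, params_point, spec)
    obs = dataset.standing
    table = ContingencyTable(
        int(np.sum((obs == 1) & (pred == 1))),
        int(np.sum((obs == 1) & (pred == 0))),
        int(np.sum((obs == 0) & (pred == 1))),
        int(np.sum((obs == 0) & (pred == 0))),
    )
    return float(np.mean(pred == obs)), table


def _cml_odds_ratio(a: int, row1: int, col1: int, n: int) -> float:
    """Conditional MLE of the odds ratio given the table margins."""
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if a == lo == hi:
        return 1.0
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0

    def score(log_psi: float) -> float:
        dist = nchypergeom_fisher(n, col1, row1, np.exp(log_psi))
        return dist.mean() - a

    return float(np.exp(brentq(score, -50, 50, xtol=1e-12)))


def _exact_ci(a: int, row1: int, col1: int, n: int, level: float = 0.95):
    """Central exact CI by inverting the noncentral hypergeometric tails."""
    alpha = (1.0 - level) / 2.0
    lo_support = max(0, row1 + col1 - n)
    hi_support = min(row1, col1)

    def upper_tail(log_psi):  # P(X >= a)
        dist = nchypergeom_fisher(n, col1, row1, np.exp(log_psi))
        return dist.sf(a - 1)

    def lower_tail(log_psi):  # P(X <= a)
        dist = nchypergeom_fisher(n, col1, row1, np.exp(log_psi))
        return dist.cdf(a)

    if a == lo_support:
        lower = 0.0
    else:
        lower = float(np.exp(brentq(lambda s: upper_tail(s) - alpha, -50, 50,
                                    xtol=1e-10)))
    if a == hi_support:
        upper = float("inf")
    else:
        upper = float(np.exp(brentq(lambda s: lower_tail(s) - alpha, -50, 50,
                                    xtol=1e-10)))
    return lower, upper


def exact_odds_ratio(
    table: ContingencyTable, level: float = 0.95, compute_ci: bool = True
):
    """Conditional-MLE odds ratio, exact central CI, and two-sided p-value.

    Matches R ``fisher.test``: the estimate maximizes the noncentral
    hypergeometric likelihood given the margins, the CI inverts the exact
    tails centrally, and the p-value sums hypergeometric probabilities of
    tables at least as extreme under independence.  Degenerate margins give a
    0 or infinite estimate with a one-sided interval.  ``compute_ci=False``
    skips the estimate/CI root-finding when only the p-value is needed.
    """
    arr = table.as_array()
    a = int(arr[0, 0])
    row1 = int(arr[0].sum())
    col1 = int(arr[:, 0].sum())
    n = int(arr.sum())
    _, p_value = fisher_exact(arr, alternative="two-sided")
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        # a zero margin: the conditional distribution is degenerate
        return float("nan"), (0.0, float("inf")), float(p_value)
    if not compute_ci:
        return float("nan"), (float("nan"), float("nan")), float(p_value)
    estimate = _cml_odds_ratio(a, row1, col1, n)
    ci = _exact_ci(a, row1, col1, n, level)
    return estimate, ci, float(p_value)


def observed_vs_expected(
    dataset: SnagDataset,
    params_point: ModelParameters,
    spec: CovariateSpec,
    group_by: str,
) -> pd.DataFrame:
    """Observed standing proportion vs mean model ``p**t`` per group level.

    ``group_by`` is one of 'species', 'cell', 'phys_class'.  Groups with no
    records simply do not appear.
    """
    if group_by not in ("species", "cell", "phys_class"):
        raise ValueError("group_by must be species, cell or phys_class")
    key = getattr(dataset, group_by)
    expected = interval_survival(dataset, params_point, spec)
    df = pd.DataFrame(
        {group_by: key, "observed": dataset.standing, "expected": expected}
    )
    out = (
        df.groupby(group_by)
        .agg(
            observed_standing=("observed", "mean"),
            expected_standing=("expected", "mean"),
            n=("observed", "size"),
        )
        .reset_index()
    )
    return out


def adequacy_report(
    dataset: SnagDataset, params_point: ModelParameters, spec: CovariateSpec
) -> AdequacyReport:
    """Full adequacy assessment at point (posterior-mean) parameters."""
    prop, table = proportion_correct(dataset, params_point, spec)
    est, ci, p = exact_odds_ratio(table)
    groups = {
        g: observed_vs_expected(dataset, params_point, spec, g)
        for g in ("species", "cell", "phys_class")
    }
    return AdequacyReport(prop, table, est, ci, p, groups)
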