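#!/usr/bin/env python
"""Adequacy of the fitted model: observed versus predicted snag fates.

At posterior-mean parameters, each snag's interval survival probability
p**t is rounded to a standing/fallen prediction; the resulting 2x2 table is
summarized by the proportion correct and the exact (conditional-MLE) odds
ratio, and the observed-vs-expected standing proportions are tabulated by
species, grid cell and physiographic class.  Outputs: results/adequacy/.
"""

import json
from pathlib import Path

from snagfall.adequacy import adequacy_report
from snagfall.cli import _point_params
from snagfall.io import read_durability_table, read_grid, read_survey
from snagfall.mcmc import PosteriorDraws

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data" / "recovery"
    grid = read_grid(data / "grid.json")
    table = read_durability_table(data / "durability.csv")
    # standardized covariate scale: skip the natural-units diameter check
    dataset, spec, _, _ = read_survey(data / "survey.csv", grid=grid,
                                      check_diameter=False)
    draws = PosteriorDraws.load(ROOT / "fit" / "draws.csv")

    params = _point_params(draws, dataset, grid, table)
    report = adequacy_report(dataset, params, spec)

    out = ROOT / "adequacy"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "adequacy.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    for name, df in report.by_group.items():
        df.to_csv(out / f"observed_vs_expected_{name}.csv", index=False)

    lo, hi = report.odds_ratio_ci
    print(f"proportion correct: {100 * report.proportion_correct:.1f}%")
    print(f"odds ratio {report.odds_ratio:.2f} "
          f"(95% CI [{lo:.2f}, {hi:.2f}], p = {report.p_value:.2g})")


if __name__ == "__main__":
    main()
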