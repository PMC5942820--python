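#!/usr/bin/env python
"""Convergence diagnostics for the fitted chains.

Computes the Brooks-Gelman-Rubin potential scale reduction factor with its
97.5% upper limit for every parameter and flags the fit as converged when
all upper limits sit below 1.05.  Writes results/diagnostics/bgr.csv.
"""

from pathlib import Path

from snagfall.mcmc import PosteriorDraws, bgr_diagnostic

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    draws = PosteriorDraws.load(ROOT / "fit" / "draws.csv",
                                ROOT / "fit" / "draws_manifest.json")
    res = bgr_diagnostic(draws, threshold=1.05)
    out = ROOT / "diagnostics"
    out.mkdir(parents=True, exist_ok=True)
    df = res.to_dataframe().sort_values("psrf_upper", ascending=False)
    df.to_csv(out / "bgr.csv", index=False)
    print(f"converged at threshold 1.05: {res.converged}")
    print("five largest upper limits:")
    print(df.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
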