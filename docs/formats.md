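# File formats

All tables are UTF-8, comma-separated CSV with '.' as the decimal mark;
structured metadata is JSON; configurations are YAML. Indices are 1-based
in files and converted to dense 0-based indices in memory.

## Survey table (`survey.csv`)

One row per snag observation.

| column          | type  | meaning / validation |
|-----------------|-------|----------------------|
| standing        | 0/1   | 1 = still standing at resurvey |
| interval_years  | float | census interval, > 0 |
| decay_class     | int   | 1–5, 1 = earliest decay stage |
| phys_class      | int   | 1-based physiographic class index |
| cell            | int   | 1-based grid-cell index (within the grid file) |
| species         | int   | 1-based species index (row of the durability table) |
| family, division| str   | optional taxonomy echo (informational) |
| AT, DIA, TPH, … | float | covariate columns; finite; DIA ≥ 12.7 cm |

Strict mode (default) rejects the file on the first invalid row, reporting
file, line and field; permissive mode drops invalid rows and reports
counts per reason.

## Grid (`grid.json`)

One of:

* `{"shape": [rows, cols]}` — rook-adjacency lattice;
* `{"n_cells": p, "adjacency": [[k, h], ...]}` — explicit 1-based edges;
* `{"n_cells": p, "cell_bounds": [[lat_min, lat_max, lon_min, lon_max], ...]}`
  — degree rectangles closed on the lower/left edge; rook adjacency is
  derived from shared edges.

## Durability table (`durability.csv`)

One row per species: `species, family, division, durability, n_sources`.
`durability` ∈ [0, 4] or empty (missing → imputed during fitting);
`division` is `angiosperm` or `gymnosperm`.

## Durability sources (`sources.csv` + `scales.yaml`)

Raw compilation input: CSV columns `source_id, species, category` (free
text); the YAML maps each `source_id` to its ordered category list, least
durable first. Ranges ("moderately to very durable") score the midpoint.

## Posterior draws (`draws.csv` + `draws_manifest.json`)

Tidy CSV `chain, draw, parameter, value`. Parameter names: `beta0`,
`rho[AT]`, `sigma_p|g|s|f|d`, `beta_dur`, `mu_d[<division>]`,
`mu_f[<family>]`, `u[j]`, `v[k]`, `w[l]` (0-based), and `dur[<species>]`
for each imputed durability on the 0–4 scale. The manifest records the
chain protocol, per-chain seeds, dataset hash, covariate centering and
per-chain acceptance reports.

## Effects (`effects.csv`, `effects_summary.json`)

Tidy per-draw comparisons: `focal, xi, response, draw, delta`; the JSON
holds means and central 95% intervals per scenario × response.

## Carbon (`*.yaml`, `sensitivity.csv`)

CarbonConfig YAML keys: `npp, mortality_rate, snag_fraction, litter_rate,
k_litter, k_snag, k_log, p_snag` (per-year rates, kg C ha⁻¹ stocks).
Sensitivity CSV: `scenario_p, delta_snag_c, delta_snag_c_pct, delta_nep`.

## Manifest (`manifest.json`)

Every pipeline output directory contains exactly one: the subcommand,
config snapshot, seeds, SHA-256 of each input file, package version and a
UTC timestamp.
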