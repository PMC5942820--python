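"""File formats and validation for the pipeline.

Survey tables, durability tables and posterior draws travel as UTF-8 CSV
('.' decimal); grids, manifests and reports as JSON; configurations as YAML.
Indices (phys_class, cell, species) are 1-based in files and 0-based in
memory.  See docs/formats.md for the column dictionaries.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .durability import DurabilitySource, DurabilityTable, score_descriptor
from .model import ALL_COVARIATES, CovariateSpec, SnagDataset, SpatialGrid
from .simulate import SimulationResult

__all__ = [
    "ValidationError",
    "RunManifest",
    "MIN_SNAG_DIAMETER_CM",
    "read_survey",
    "write_survey",
    "read_grid",
    "write_grid",
    "read_durability_table",
    "write_durability_table",
    "read_durability_sources",
    "write_simulation",
    "file_sha256",
]

#: minimum stem diameter at breast height for a bole to count as a snag
MIN_SNAG_DIAMETER_CM = 12.7


class ValidationError(ValueError):
    """Input failed validation; message names file, row and field."""


@dataclass
class RunManifest:
    """Provenance snapshot written once per pipeline output directory."""

    command: str
    config: Mapping
    seeds: Sequence[int]
    input_hashes: Mapping[str, str]
    version: str
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path

    @classmethod
    def read(cls, directory) -> "RunManifest":
        with open(Path(directory) / "manifest.json") as fh:
            return cls(**json.load(fh))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# survey tables
# ---------------------------------------------------------------------------

_REQUIRED_SURVEY_COLS = (
    "standing",
    "interval_years",
    "decay_class",
    "phys_class",
    "cell",
    "species",
)


def _row_problems(df: pd.DataFrame, check_diameter: bool = True) -> pd.Series:
    """Per-row list of validation failures (empty list = clean row)."""
    problems = [[] for _ in range(len(df))]

    def flag(mask, message):
        for i in np.flatnonzero(np.asarray(mask)):
            problems[i].append(message)

    flag(~df["standing"].isin([0, 1]), "standing not in {0,1}")
    flag(~(df["interval_years"] > 0), "interval_years not > 0")
    flag(~df["decay_class"].isin([1, 2, 3, 4, 5]), "decay_class not in 1..5")
    for col in ("phys_class", "cell", "species"):
        flag(~(df[col] >= 1), f"{col} not a 1-based positive index")
    if check_diameter and "DIA" in df.columns:
        flag(df["DIA"] < MIN_SNAG_DIAMETER_CM,
             f"DIA below the {MIN_SNAG_DIAMETER_CM} cm snag threshold")
    cov_cols = [c for c in df.columns if c in ALL_COVARIATES]
    for col in cov_cols:
        flag(~np.isfinite(df[col].to_numpy(dtype=float)), f"{col} not finite")
    return pd.Series(problems, index=df.index)


def read_survey(
    path,
    covariates: Sequence[str] | None = None,
    grid: SpatialGrid | None = None,
    strict: bool = True,
    check_diameter: bool = True,
):
    """Read and validate a survey CSV.

    Returns ``(dataset, spec, index_maps, report)`` where ``index_maps`` maps
    each of phys_class/cell/species to the original 1-based labels in dense
    internal order and ``report`` counts rejected rows per reason.  In strict
    mode any invalid row raises :class:`ValidationError`; in permissive mode
    invalid rows are dropped and counted.  When a ``grid`` is supplied, cell
    indices are kept aligned to it (1..n_cells) instead of being remapped.
    ``check_diameter=False`` skips the 12.7 cm snag threshold, for surveys
    whose covariates are on a standardized rather than natural scale.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_SURVEY_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if covariates is None:
        covariates = [c for c in ALL_COVARIATES if c in df.columns]
    for c in covariates:
        if c not in df.columns:
            raise ValidationError(f"{path}: missing covariate column {c!r}")
    if grid is not None:
        bad = ~df["cell"].between(1, grid.n_cells)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValidationError(
                f"{path}: line {row}: field 'cell' outside 1..{grid.n_cells}"
            )

    problems = _row_problems(df, check_diameter)
    bad_mask = problems.str.len() > 0
    if bad_mask.any() and strict:
        first = int(df.index[bad_mask][0])
        raise ValidationError(
            f"{path}: line {first + 2}: " + "; ".join(problems.iloc[first])
            + f" ({int(bad_mask.sum())} invalid rows in total)"
        )
    report = {
        "n_read": int(len(df)),
        "n_rejected": int(bad_mask.sum()),
        "reasons": pd.Series(
            [m for ms in problems[bad_mask] for m in ms]
        ).value_counts().to_dict()
        if bad_mask.any()
        else {},
    }
    df = df.loc[~bad_mask].reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"{path}: no valid rows after validation")

    index_maps: dict[str, list] = {}
    dense = {}
    for col in ("phys_class", "species"):
        codes, uniques = pd.factorize(df[col], sort=True)
        dense[col] = codes
        index_maps[col] = uniques.tolist()
    if grid is None:
        codes, uniques = pd.factorize(df["cell"], sort=True)
        dense["cell"] = codes
        index_maps["cell"] = uniques.tolist()
    else:
        dense["cell"] = df["cell"].to_numpy() - 1
        index_maps["cell"] = list(range(1, grid.n_cells + 1))

    spec = CovariateSpec.from_data(covariates, df)
    dataset = SnagDataset(
        df["standing"].to_numpy(),
        df["interval_years"].to_numpy(dtype=float),
        df[list(covariates)].to_numpy(dtype=float),
        dense["phys_class"],
        dense["cell"],
        dense["species"],
        df["decay_class"].to_numpy(),
        spec,
    )
    return dataset, spec, index_maps, report


def write_survey(
    dataset: SnagDataset, path, durability_table: DurabilityTable | None = None
) -> None:
    """Write a survey CSV (1-based indices; taxonomy columns if available)."""
    df = dataset.to_dataframe()
    for col in ("phys_class", "cell", "species"):
        df[col] = df[col] + 1
    if durability_table is not None:
        tab = durability_table.table
        df["family"] = tab["family"].to_numpy()[dataset.species]
        df["division"] = tab["division"].to_numpy()[dataset.species]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def _bounds_adjacency(bounds) -> list[set[int]]:
    """Rook adjacency from cell rectangles: cells sharing an edge segment."""
    eps = 1e-9
    n = len(bounds)
    sets: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        la0, la1, lo0, lo1 = bounds[i]
        for j in range(i + 1, n):
            lb0, lb1, mo0, mo1 = bounds[j]
            lat_touch = abs(la1 - lb0) < eps or abs(lb1 - la0) < eps
            lon_touch = abs(lo1 - mo0) < eps or abs(mo1 - lo0) < eps
            lat_overlap = min(la1, lb1) - max(la0, lb0) > eps
            lon_overlap = min(lo1, mo1) - max(lo0, mo0) > eps
            if (lat_touch and lon_overlap) or (lon_touch and lat_overlap):
                sets[i].add(j)
                sets[j].add(i)
    return sets


def read_grid(path) -> SpatialGrid:
    """Grid JSON: n_cells plus an adjacency list, a shape, or cell bounds."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if "shape" in raw:
        return SpatialGrid.rectangular(*raw["shape"])
    n = raw.get("n_cells")
    if n is None:
        raise ValidationError(f"{path}: grid JSON needs 'n_cells' or 'shape'")
    if "adjacency" in raw:
        sets: list[set[int]] = [set() for _ in range(n)]
        for k, h in raw["adjacency"]:  # 1-based pairs
            sets[k - 1].add(h - 1)
            sets[h - 1].add(k - 1)
        return SpatialGrid(n, sets)
    if "cell_bounds" in raw:
        bounds = raw["cell_bounds"]
        if len(bounds) != n:
            raise ValidationError(f"{path}: cell_bounds length != n_cells")
        return SpatialGrid(n, _bounds_adjacency(bounds), cell_bounds=bounds)
    raise ValidationError(f"{path}: grid JSON needs adjacency or cell_bounds")


def write_grid(grid: SpatialGrid, path) -> None:
    payload = {
        "n_cells": grid.n_cells,
        "adjacency": [[int(k) + 1, int(h) + 1] for k, h in grid.edges],
    }
    if grid.cell_bounds is not None:
        payload["cell_bounds"] = [list(map(float, b)) for b in grid.cell_bounds]
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# durability tables and sources
# ---------------------------------------------------------------------------


def read_durability_table(path) -> DurabilityTable:
    return DurabilityTable(pd.read_csv(path))


def write_durability_table(table: DurabilityTable, path) -> None:
    table.table.to_csv(path, index=False)


def read_durability_sources(csv_path, scales_yaml) -> list[DurabilitySource]:
    """Score a raw sources CSV against per-source ordered-category scales.

    The CSV has columns source_id, species, category (free text); the YAML
    maps each source_id to its ordered category list (least durable first).
    """
    df = pd.read_csv(csv_path)
    for col in ("source_id", "species", "category"):
        if col not in df.columns:
            raise ValidationError(f"{csv_path}: missing column {col!r}")
    with open(scales_yaml) as fh:
        scales = yaml.safe_load(fh)
    out = []
    for i, row in df.iterrows():
        sid = row["source_id"]
        if sid not in scales:
            raise ValidationError(
                f"{csv_path}: line {i + 2}: no scale configured for source {sid!r}"
            )
        try:
            rank = score_descriptor(scales[sid], row["category"])
        except ValueError as exc:
            raise ValidationError(f"{csv_path}: line {i + 2}: {exc}") from exc
        out.append(DurabilitySource(sid, row["species"], rank))
    return out


def write_simulation(result: SimulationResult, out_dir) -> dict[str, Path]:
    """Persist a synthetic survey: survey/durability CSV, grid and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": out / "survey.csv",
        "durability": out / "durability.csv",
        "grid": out / "grid.json",
        "truth": out / "truth.json",
    }
    write_survey(result.dataset, paths["survey"], result.durability_table)
    write_durability_table(result.durability_table, paths["durability"])
    write_grid(result.grid, paths["grid"])
    te = result.config.true_params
    truth = {
        "beta0": te.beta0,
        "rho": dict(te.rho),
        "sigma_p": te.sigma_p,
        "sigma_g": te.sigma_g,
        "sigma_s": te.sigma_s,
        "beta_dur": te.beta_dur,
        "true_durability": result.true_durability.tolist(),
        "seed": result.config.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
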