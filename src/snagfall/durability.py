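"""Compile species wood-durability scores onto a single 0-4 ordinal scale.

Published durability classifications use heterogeneous vocabularies
("non-resistant", "moderately durable", ...).  Each source supplies an ordered
category scale; the least durable category maps to 0 and the most durable to
4, with linear interpolation for sources with fewer than five levels and
midpoints for ranged descriptors ("moderately to very durable").  Species
with more than one source get the arithmetic mean; species with no source get
a missing value and are imputed downstream through the taxonomic hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DurabilitySource",
    "DurabilityTable",
    "score_descriptor",
    "aggregate_species",
    "build_table",
]


@dataclass(frozen=True)
class DurabilitySource:
    """One source's durability classification of one species."""

    source_id: str
    species: str
    descriptor_rank: float

    def __post_init__(self) -> None:
        r = self.descriptor_rank
        if not (0 <= r <= 4) or (2 * r) != int(2 * r):
            raise ValueError(
                f"descriptor_rank must lie in [0, 4] in steps of 0.5, got {r}"
            )


@dataclass
class DurabilityTable:
    """Per-species mean durability plus taxonomy.

    ``durability`` is NaN where no source covered the species; every species
    must still carry a family and a division (angiosperm or gymnosperm).
    """

    table: pd.DataFrame  # columns: species, family, division, durability, n_sources

    def __post_init__(self) -> None:
        required = {"species", "family", "division", "durability", "n_sources"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"durability table missing columns {sorted(missing)}")
        bad_div = ~self.table["division"].isin(["angiosperm", "gymnosperm"])
        if bad_div.any():
            raise ValueError(
                f"unknown division values: {self.table.loc[bad_div, 'division'].unique()}"
            )
        dur = self.table["durability"]
        if ((dur < 0) | (dur > 4)).any():
            raise ValueError("durability values must lie in [0, 4]")

    @property
    def species(self) -> list[str]:
        return self.table["species"].tolist()

    @property
    def observed_mask(self) -> np.ndarray:
        return self.table["durability"].notna().to_numpy()

    @property
    def durability(self) -> np.ndarray:
        return self.table["durability"].to_numpy(dtype=float)

    def dur_bar(self) -> float:
        """Mean durability across species with an observed estimate."""
        obs = self.table["durability"].dropna()
        if obs.empty:
            raise ValueError("no observed durabilities to average")
        return float(obs.mean())

    def taxonomy_indices(self) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
        """0-based (family_of_species, division_of_family) index arrays.

        Families are ordered by first appearance; divisions are fixed as
        [angiosperm, gymnosperm].
        """
        families = list(dict.fromkeys(self.table["family"]))
        divisions = ["angiosperm", "gymnosperm"]
        fam_idx = np.array([families.index(f) for f in self.table["family"]])
        div_of_fam = np.empty(len(families), dtype=int)
        for i, fam in enumerate(families):
            divs = set(self.table.loc[self.table["family"] == fam, "division"])
            if len(divs) != 1:
                raise ValueError(f"family {fam!r} spans multiple divisions: {divs}")
            div_of_fam[i] = divisions.index(divs.pop())
        return fam_idx, div_of_fam, families, divisions


def score_descriptor(
    source_scale: Sequence[str], category_or_range: str | Sequence[str]
) -> float:
    """Rank one source's category (or two-category range) on the 0-4 scale.

    The source's least durable category scores 0 and its most durable scores
    4; scales with fewer than five levels are spread linearly over [0, 4].
    A range of two categories scores the midpoint of their ranks.
    """
    scale = [c.strip().lower() for c in source_scale]
    if len(scale) < 2:
        raise ValueError("source scale needs at least two ordered categories")
    step = 4.0 / (len(scale) - 1)

    def one(cat: str) -> float:
        key = cat.strip().lower()
        if key not in scale:
            raise ValueError(
                f"unknown category {cat!r}; valid categories: {source_scale}"
            )
        return scale.index(key) * step

    if isinstance(category_or_range, str) and " to " in category_or_range.lower():
        parts = [p for p in category_or_range.lower().split(" to ") if p.strip()]
        if len(parts) == 2:
            return (one(parts[0]) + one(parts[1])) / 2.0
    if not isinstance(category_or_range, str):
        cats = list(category_or_range)
        if len(cats) != 2:
            raise ValueError("a ranged descriptor must span exactly two categories")
        return (one(cats[0]) + one(cats[1])) / 2.0
    return one(category_or_range)


def aggregate_species(scores: Sequence[DurabilitySource] | Sequence[float]) -> float:
    """Arithmetic mean of a species' source ranks; NaN when no source."""
    ranks = [
        s.descriptor_rank if isinstance(s, DurabilitySource) else float(s)
        for s in scores
    ]
    if not ranks:
        return float("nan")
    return float(np.mean(ranks))


def build_table(
    sources: Sequence[DurabilitySource],
    taxonomy: Mapping[str, tuple[str, str]],
    survey_species: Sequence[str] | None = None,
) -> DurabilityTable:
    """Assemble the species durability table.

    Parameters
    ----------
    sources:
        Scored source rows.  Duplicate (species, source) pairs are an error.
    taxonomy:
        species -> (family, division) mapping; must cover every species in
        ``sources`` and in ``survey_species``.
    survey_species:
        Species to include even without any source (rows flagged for
        imputation).  Defaults to the sourced species only.
    """
    seen: set[tuple[str, str]] = set()
    for s in sources:
        key = (s.species, s.source_id)
        if key in seen:
            raise ValueError(f"duplicate (species, source) row: {key}")
        seen.add(key)

    all_species = list(dict.fromkeys(
        [s.species for s in sources] + list(survey_species or [])
    ))
    missing_tax = [sp for sp in all_species if sp not in taxonomy]
    if missing_tax:
        raise ValueError(f"species absent from taxonomy: {missing_tax}")

    by_species: dict[str, list[DurabilitySource]] = {sp: [] for sp in all_species}
    for s in sources:
        by_species[s.species].append(s)

    rows = []
    for sp in all_species:
        fam, div = taxonomy[sp]
        rows.append(
            {
                "species": sp,
                "family": fam,
                "division": div,
                "durability": aggregate_species(by_species[sp]),
                "n_sources": len(by_species[sp]),
            }
        )
    return DurabilityTable(pd.DataFrame(rows))
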