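"""Build the analysis-ready species x trait table from per-record means.

The raw input is a set of records, one per (species, trait, sex) mean with
the number of animals behind it.  The table builder applies the study's
inclusion rules in a fixed, documented order:

1. keep female records (strict mode drops unlabeled-sex rows);
2. pool duplicate (species, trait) records by n-weighted mean;
3. drop cells backed by fewer than ``min_animals`` animals;
4. drop species without body mass (mass is the mandatory predictor);
5. drop traits with fewer than ``min_species`` qualifying species --
   a trait can fail this solely because step 3 thinned it;
6. log10-transform everything.

The target species enters through a separate native-scale value map, so the
captive-population filters never apply to it.  A JSON-able audit log records
every filter decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["TraitTable", "build_table", "trait_subset", "read_table", "write_table"]

RECORD_COLUMNS = ["species", "trait", "sex", "value", "n"]
MASS = "mass"


@dataclass
class TraitTable:
    """Species x {mass, traits} on log10 scale, with per-cell missingness.

    ``data`` is indexed by species name; the designated target species (if
    any) is a regular row whose label is stored in ``target``.
    """

    data: pd.DataFrame
    target: str | None = None
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if MASS not in self.data.columns:
            raise ValueError("TraitTable requires a 'mass' column")
        if self.target is not None and self.target not in self.data.index:
            raise ValueError(f"target {self.target!r} not present in table")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c != MASS]

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def without_target(self) -> pd.DataFrame:
        if self.target is None:
            return self.data
        return self.data.drop(index=self.target)


def build_table(
    records: pd.DataFrame,
    target_values: Mapping[str, float] | None = None,
    *,
    target_name: str = "target",
    min_animals: int = 10,
    min_species: int = 10,
    strict_sex: bool = True,
) -> TraitTable:
    """Apply the inclusion filters and log10 transform to raw records.

    ``records`` must have columns species, trait, sex, value, n; values are
    on native (pre-log) scale and must be positive.  ``target_values`` maps
    trait name -> native-scale value for the target species (mass included);
    the target row bypasses the record filters.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("empty record set")
    rec = records.copy()
    rec["n"] = rec["n"].astype(int)
    if (rec["n"] < 1).any():
        raise ValueError("record with n_animals < 1")
    bad = rec[~(rec["value"] > 0) | ~np.isfinite(rec["value"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"non-positive or non-finite value for species {r['species']!r}, "
            f"trait {r['trait']!r}: log10 undefined"
        )

    audit: dict = {"filters": {"min_animals": min_animals, "min_species": min_species,
                               "strict_sex": strict_sex}, "traits": {}}

    sex = rec["sex"].astype(str).str.strip().str.lower()
    is_female = sex.isin({"f", "female"})
    if strict_sex:
        keep = is_female
    else:
        keep = is_female | sex.isin({"", "nan", "none", "unknown"})
    audit["rows_dropped_sex"] = int((~keep).sum())
    rec = rec[keep]
    if len(rec) == 0:
        raise ValueError("no records left after sex filter")

    # pool duplicate (species, trait) records: n-weighted mean, n summed
    grp = rec.groupby(["species", "trait"], sort=True)
    pooled = grp.apply(
        lambda g: pd.Series(
            {"value": np.average(g["value"], weights=g["n"]), "n": g["n"].sum()}
        ),
        include_groups=False,
    ).reset_index()

    enough = pooled["n"] >= min_animals
    audit["cells_dropped_animals"] = int((~enough).sum())
    pooled = pooled[enough]

    wide = pooled.pivot(index="species", columns="trait", values="value")
    if MASS not in wide.columns:
        raise ValueError("no qualifying body-mass data")
    has_mass = wide[MASS].notna()
    audit["species_dropped_no_mass"] = sorted(wide.index[~has_mass])
    wide = wide[has_mass]

    keep_cols = [MASS]
    for trait in [c for c in wide.columns if c != MASS]:
        n_sp = int(wide[trait].notna().sum())
        if n_sp >= min_species:
            keep_cols.append(trait)
            audit["traits"][trait] = {"kept": True, "n_species": n_sp}
        else:
            audit["traits"][trait] = {"kept": False, "n_species": n_sp,
                                      "reason": f"fewer than {min_species} species"}
    wide = wide[keep_cols]
    if len(wide) == 0 or len(keep_cols) == 1:
        raise ValueError("empty table after filtering")

    table = np.log10(wide)
    target = None
    if target_values is not None:
        tv = {k: v for k, v in target_values.items() if k in table.columns}
        if MASS not in tv:
            raise ValueError("target_values must include 'mass'")
        for k, v in tv.items():
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"non-positive target value for trait {k!r}")
        table.loc[target_name] = {k: np.log10(v) for k, v in tv.items()}
        target = target_name
    table = table.sort_index()
    table.columns.name = None
    return TraitTable(table, target=target, audit=audit)


def trait_subset(table: TraitTable, trait: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Species with data for ``trait``, with their mass and trait vectors.

    Row order follows the table's (sorted) species order and is stable.
    """
    if trait not in table.traits:
        raise KeyError(f"unknown trait: {trait!r}")
    sub = table.data[[MASS, trait]].dropna()
    return list(sub.index), sub[MASS].to_numpy(), sub[trait].to_numpy()


def write_table(table: TraitTable, path: str) -> None:
    """Write the table as CSV plus a JSON audit sidecar."""
    table.data.to_csv(path, index_label="species")
    side = {"target": table.target, "audit": table.audit}
    with open(str(path) + ".audit.json", "w") as fh:
        json.dump(side, fh, indent=2, default=str)


def read_table(path: str, target: str | None = None) -> TraitTable:
    df = pd.read_csv(path, index_col="species")
    return TraitTable(df, target=target)
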