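"""Tabular I/O and diet-category assignment.

Trait tables are taxon-by-trait matrices with a unit tag per trait
(g, mm, mm2, microstrain, deg, or dimensionless).  Diet compositions
follow the EltonTraits 1.0 field layout (percent of the diet from each
food source) and are mapped to a single categorical diet by fixed
thresholds; tetrapod prey is the sum of the ectotherm and endotherm
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "DietComposition",
    "DIET_CATEGORIES",
    "TraitTableError",
    "read_trait_table",
    "write_trait_table",
    "assign_diet_category",
    "read_strain_field",
]

#: Closed vocabulary of diet categories.
DIET_CATEGORIES = (
    "Folivore",
    "Frugivore",
    "Generalist",
    "GranivoreH",
    "GranivoreS",
    "Granivore",
    "Invertivore",
    "Nectarivore",
    "Piscivore",
    "Scavenger",
    "TetrapodHunter",
    "Unclassified",
)

#: Units for which negative values are physically impossible.
_NONNEGATIVE_UNITS = {"g", "mm", "mm2", "microstrain"}


class TraitTableError(ValueError):
    """Raised for malformed trait-table input."""


@dataclass
class TraitTable:
    """Taxa x named numeric traits, with a unit tag per trait.

    ``data`` is indexed by unique taxon ids; ``units`` maps each column
    to its unit tag.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise TraitTableError(f"duplicate taxon ids: {dupes}")
        for col in self.data.columns:
            if col not in self.units:
                raise TraitTableError(f"no unit tag for trait {col!r}")
            if self.units[col] in _NONNEGATIVE_UNITS:
                vals = self.data[col].to_numpy(dtype=float)
                if np.any(vals[~np.isnan(vals)] < 0):
                    raise TraitTableError(
                        f"negative value in trait {col!r} ({self.units[col]})"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_trait_table(path, schema: dict) -> TraitTable:
    """Read a CSV/TSV trait table (delimiter auto-detected from the header).

    ``schema`` maps trait column names to unit tags; only those columns
    are retained (plus the first column, taken as the taxon id).  Any
    non-numeric cell in a schema column is a hard error naming its
    row and column.
    """
    delim = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, dtype=str, comment="#")
    raw = raw.dropna(how="all")
    id_col = raw.columns[0]
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise TraitTableError(f"missing trait columns: {missing}")
    out = {}
    for col in schema:
        vals = []
        for row_label, cell in zip(raw[id_col], raw[col]):
            try:
                vals.append(float(cell))
            except (TypeError, ValueError):
                raise TraitTableError(
                    f"non-numeric value {cell!r} in row {row_label!r}, "
                    f"column {col!r}"
                ) from None
        out[col] = vals
    data = pd.DataFrame(out, index=pd.Index(raw[id_col], name=id_col))
    return TraitTable(data=data, units=dict(schema))


def write_trait_table(table: TraitTable, path) -> None:
    """Write a trait table back to CSV (12 significant digits)."""
    table.data.to_csv(path, float_format="%.12g")


# ----------------------------------------------------------------------
# diet compositions
# ----------------------------------------------------------------------

_ELTON_FIELDS = (
    "Diet-Inv",
    "Diet-Vend",
    "Diet-Vect",
    "Diet-Vfish",
    "Diet-Scav",
    "Diet-Fruit",
    "Diet-Nect",
    "Diet-Seed",
    "Diet-PlantO",
)


@dataclass
class DietComposition:
    """Percent of the diet from each EltonTraits food-source field.

    ``husking`` records whether the bird husks seeds before swallowing
    (True/False) or is unknown (None); it is an input coding taken from
    feeding descriptions, never computed.
    """

    percentages: dict
    husking: bool | None = None

    def __post_init__(self):
        total = 0.0
        for name in _ELTON_FIELDS:
            v = float(self.percentages.get(name, 0.0))
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} = {v} outside [0, 100]")
            total += v
        total += float(self.percentages.get("Diet-Vunk", 0.0))
        if not 95.0 <= total <= 105.0:
            raise ValueError(f"diet percentages sum to {total}, outside [95, 105]")

    def get(self, name: str) -> float:
        return float(self.percentages.get(name, 0.0))

    @property
    def tetrapod(self) -> float:
        """Diet-Tetr: endotherm + ectotherm tetrapod prey (Diet-Vunk excluded)."""
        return self.get("Diet-Vend") + self.get("Diet-Vect")


def assign_diet_category(comp: DietComposition, split_granivores: bool = True) -> str:
    """Assign exactly one diet category from threshold rules.

    Thresholds are inclusive.  Specific thresholds are checked before the
    Generalist rule (every field <= 40%); if two specific thresholds fire
    simultaneously the bird is left Unclassified rather than forced into
    one category, and Unclassified is also the fall-through.
    """
    fired = []
    if comp.get("Diet-PlantO") >= 60:
        fired.append("Folivore")
    if comp.get("Diet-Fruit") >= 60:
        fired.append("Frugivore")
    if comp.get("Diet-Seed") >= 70:
        if split_granivores:
            if comp.husking is True:
                fired.append("GranivoreH")
            elif comp.husking is False:
                fired.append("GranivoreS")
            else:
                fired.append("Granivore")
        else:
            fired.append("Granivore")
    if comp.get("Diet-Inv") >= 60:
        fired.append("Invertivore")
    if comp.get("Diet-Nect") >= 60:
        fired.append("Nectarivore")
    if comp.get("Diet-Vfish") >= 50:
        fired.append("Piscivore")
    if comp.get("Diet-Scav") >= 50:
        fired.append("Scavenger")
    if comp.tetrapod >= 60:
        fired.append("TetrapodHunter")
    if len(fired) == 1:
        return fired[0]
    if len(fired) > 1:
        return "Unclassified"
    fields = [comp.get(f) for f in _ELTON_FIELDS] + [comp.tetrapod]
    if all(v <= 40 for v in fields):
        return "Generalist"
    return "Unclassified"


# ----------------------------------------------------------------------
# finite-element strain tables
# ----------------------------------------------------------------------

def read_strain_field(path):
    """Read a per-element strain table (element_id, area, strain columns).

    Areas are mm^2 and must be strictly positive; strain is microstrain.
    Returns a :class:`trophotax.fea.StrainField`.
    """
    from .fea import StrainField  # local import to avoid a cycle

    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    required = {"element_id", "area", "strain"}
    missing = required - set(df.columns)
    if missing:
        raise TraitTableError(f"strain table missing columns: {sorted(missing)}")
    return StrainField(
        element_id=df["element_id"].to_numpy(),
        area=df["area"].to_numpy(dtype=float),
        strain=df["strain"].to_numpy(dtype=float),
    )
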