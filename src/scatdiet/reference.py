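"""Ingredient reference table: correction factors and proximate composition.

Every downstream computation is parameterized by a table of dietary
ingredients.  Each ingredient carries

* a *correction factor* (``cf``): grams of dry matter ingested per millilitre
  of fecal residue, which corrects fecal volume proportions for differential
  digestibility (highly digestible items leave little residue, so their
  correction factor is large);
* a proximate composition on a dry-matter basis: crude protein (CP), crude
  fat (ether extract, EE), ash, crude fiber, and total dietary fiber (TDF),
  all as % DM;
* a kingdom flag (plant / vertebrate / invertebrate / egg / miscellaneous)
  that selects the digestible-carbohydrate (NfE) rule, and one of six
  primary reporting categories.

Beware the field's overloaded abbreviation "CF": here ``cf`` is always the
correction factor and ``cfiber_pct`` the crude fiber content.  They are
unrelated quantities with different units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

KINGDOMS = frozenset({"plant", "vertebrate", "invertebrate", "egg", "miscellaneous"})
ANIMAL_KINGDOMS = frozenset({"vertebrate", "invertebrate", "egg"})
CATEGORIES = (
    "fruit",
    "insects",
    "vertebrates",
    "natural_vegetation",
    "anthropogenic_vegetation",
    "other",
)

REFERENCE_COLUMNS = [
    "ingredient_id",
    "display_name",
    "kingdom",
    "primary_category",
    "cf",
    "dm_pct",
    "cp_pct",
    "ee_pct",
    "ash_pct",
    "cfiber_pct",
    "tdf_pct",
    "provenance",
]

# Tolerance for the mass-balance checks below; compositions are literature
# values quoted to one decimal, so equality is only meaningful to ~1e-6.
_BALANCE_TOL = 1e-6


class SchemaError(ValueError):
    """A delimited input file does not match its documented header."""


class ValidationError(ValueError):
    """A record violates a domain invariant; the message names the record."""


@dataclass(frozen=True)
class IngredientDef:
    """One dietary ingredient with its correction factor and composition.

    ``cf`` is ``None`` only for the designated miscellaneous ingredient,
    which stands for unidentifiable matter and has no composition either.
    """

    ingredient_id: str
    display_name: str
    kingdom: str
    primary_category: str
    cf: float | None
    dm_pct: float | None = None
    cp_pct: float | None = None
    ee_pct: float | None = None
    ash_pct: float | None = None
    cfiber_pct: float | None = None
    tdf_pct: float | None = None
    provenance: str = ""

    @property
    def is_misc(self) -> bool:
        return self.kingdom == "miscellaneous"

    @property
    def is_animal(self) -> bool:
        return self.kingdom in ANIMAL_KINGDOMS

    def violations(self) -> list[str]:
        """Return human-readable invariant violations for this row."""
        v: list[str] = []
        i = self.ingredient_id
        if self.kingdom not in KINGDOMS:
            v.append(f"{i}: unknown kingdom {self.kingdom!r}")
            return v
        if self.primary_category not in CATEGORIES:
            v.append(f"{i}: unknown primary_category {self.primary_category!r}")
        if self.is_misc:
            if self.cf is not None:
                v.append(f"{i}: miscellaneous must not carry a correction factor")
            return v
        if self.cf is None or not self.cf > 0:
            v.append(f"{i}: correction factor must be > 0 (got {self.cf!r})")
        for name in ("dm_pct", "cp_pct", "ee_pct", "ash_pct", "cfiber_pct", "tdf_pct"):
            val = getattr(self, name)
            if val is None:
                v.append(f"{i}: missing {name}")
            elif not (0 <= val <= 100):
                v.append(f"{i}: {name}={val} outside [0, 100]")
        if any(getattr(self, n) is None for n in ("cp_pct", "ee_pct", "ash_pct", "tdf_pct")):
            return v
        if self.dm_pct is not None and not self.dm_pct > 0:
            v.append(f"{i}: dm_pct must be > 0")
        if self.kingdom == "plant":
            total = self.cp_pct + self.ee_pct + self.ash_pct + self.tdf_pct
            if total > 100 + _BALANCE_TOL:
                v.append(
                    f"{i}: plant CP+EE+Ash+TDF = {total:.2f} > 100 (negative NfE)"
                )
        else:  # vertebrate, invertebrate, egg: TDF overlaps CP, not subtracted
            total = self.cp_pct + self.ee_pct + self.ash_pct
            if total > 100 + _BALANCE_TOL:
                v.append(
                    f"{i}: animal CP+EE+Ash = {total:.2f} > 100 (negative NfE)"
                )
        if (
            self.tdf_pct is not None
            and self.cfiber_pct is not None
            and self.tdf_pct < self.cfiber_pct - _BALANCE_TOL
        ):
            v.append(
                f"{i}: TDF ({self.tdf_pct}) < crude fiber ({self.cfiber_pct}); "
                "TDF is the more complete fiber measure"
            )
        return v


@dataclass
class ReferenceTable:
    """Keyed collection of :class:`IngredientDef` with exactly one misc row."""

    ingredients: dict[str, IngredientDef] = field(default_factory=dict)

    def __contains__(self, ingredient_id: str) -> bool:
        return ingredient_id in self.ingredients

    def __getitem__(self, ingredient_id: str) -> IngredientDef:
        try:
            return self.ingredients[ingredient_id]
        except KeyError:
            raise KeyError(f"unknown ingredient {ingredient_id!r}") from None

    def __iter__(self):
        return iter(self.ingredients.values())

    def __len__(self) -> int:
        return len(self.ingredients)

    @property
    def ids(self) -> list[str]:
        return list(self.ingredients)

    @property
    def misc_id(self) -> str | None:
        for ing in self:
            if ing.is_misc:
                return ing.ingredient_id
        return None

    def identified_ids(self) -> list[str]:
        return [i.ingredient_id for i in self if not i.is_misc]

    def category_of(self, ingredient_id: str) -> str:
        return self[ingredient_id].primary_category

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(ing, c) for c in REFERENCE_COLUMNS} for ing in self
        ]
        return pd.DataFrame(rows, columns=REFERENCE_COLUMNS)


def validate_reference(table: ReferenceTable) -> list[str]:
    """Collect invariant violations; empty list means the table is valid.

    Reports rather than raises so callers can surface every problem in one
    pass.  Order-independent over rows apart from the reporting order.
    """
    out: list[str] = []
    for ing in table:
        out.extend(ing.violations())
    misc = [i.ingredient_id for i in table if i.is_misc]
    if len(misc) != 1:
        out.append(
            f"table must designate exactly one miscellaneous ingredient, found {len(misc)}"
        )
    return out


def _rows_to_table(rows: Iterable[dict], source: str) -> ReferenceTable:
    ingredients: dict[str, IngredientDef] = {}
    problems: list[str] = []
    for row in rows:
        ing = IngredientDef(**row)
        if ing.ingredient_id in ingredients:
            problems.append(f"{source}: duplicate ingredient_id {ing.ingredient_id!r}")
            continue
        problems.extend(ing.violations())
        ingredients[ing.ingredient_id] = ing
    table = ReferenceTable(ingredients)
    misc = [i.ingredient_id for i in table if i.is_misc]
    if len(misc) != 1:
        problems.append(
            f"{source}: exactly one miscellaneous ingredient required, found {len(misc)}"
        )
    if problems:
        raise ValidationError("; ".join(problems))
    return table


def load_reference(path: str | Path) -> ReferenceTable:
    """Load and validate an ingredient reference CSV.

    The schema is ``ingredient_id,display_name,kingdom,primary_category,cf,
    dm_pct,cp_pct,ee_pct,ash_pct,cfiber_pct,tdf_pct,provenance`` with percent
    fields on a 0-100 scale.  Rows failing any invariant abort the load with
    a message naming each offending ingredient.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"ingredient_id": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns and c != "provenance"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    df["provenance"] = df["provenance"].fillna("")
    rows = []
    for rec in df.to_dict("records"):
        row = {c: rec[c] for c in REFERENCE_COLUMNS}
        for num in ("cf", "dm_pct", "cp_pct", "ee_pct", "ash_pct", "cfiber_pct", "tdf_pct"):
            row[num] = None if pd.isna(row[num]) else float(row[num])
        rows.append(row)
    return _rows_to_table(rows, str(path))


# Packaged illustrative table.  Correction factors and compositions are
# literature-plausible values for a Scandinavian brown bear diet and are
# meant for testing and demonstration; analyses of real scat collections
# should supply their own reference CSV.  Fiber values sit inside published
# per-category ranges (berries 23.2-45.6, insects 2.7-26.6, vertebrates
# 6.3-17.3, natural vegetation 13.3-59.4, anthropogenic 11.8-24.7 % DM) and
# vertebrate fat stays at or below the 24.3 % DM prey maximum.
_BUILTIN_CSV = """\
ingredient_id,display_name,kingdom,primary_category,cf,dm_pct,cp_pct,ee_pct,ash_pct,cfiber_pct,tdf_pct,provenance
bilberry,Bilberry (Vaccinium myrtillus),plant,fruit,0.55,13.0,5.5,4.0,2.5,15.0,30.0,illustrative
lingonberry,Lingonberry (Vaccinium vitis-idaea),plant,fruit,0.50,14.0,4.5,3.5,2.0,14.0,28.0,illustrative
crowberry,Crowberry (Empetrum nigrum),plant,fruit,0.50,12.0,5.0,5.0,2.0,20.0,40.0,illustrative
moose,Moose (Alces alces),vertebrate,vertebrates,2.00,30.0,55.0,15.0,12.0,0.0,12.0,illustrative
small_mammal,Small mammals,vertebrate,vertebrates,1.80,30.0,60.0,16.0,12.0,0.0,10.0,illustrative
bear_hair,Bear hair,vertebrate,vertebrates,0.60,90.0,90.0,3.0,3.0,0.0,16.0,illustrative
formica,Ants (Formica spp.),invertebrate,insects,0.80,28.0,50.0,12.0,6.0,5.0,15.0,illustrative
wasp,Wasps and bees,invertebrate,insects,0.80,25.0,55.0,18.0,5.0,4.0,10.0,illustrative
graminoid,Graminoids,plant,natural_vegetation,0.25,22.0,12.0,2.5,7.0,30.0,55.0,illustrative
forb,Forbs and leaves,plant,natural_vegetation,0.30,20.0,15.0,3.0,8.0,25.0,45.0,illustrative
mushroom,Mushrooms,plant,natural_vegetation,0.60,10.0,25.0,3.0,8.0,10.0,30.0,illustrative
oats,Oats,plant,anthropogenic_vegetation,1.00,88.0,12.0,5.0,3.0,11.0,22.0,illustrative
maize,Maize,plant,anthropogenic_vegetation,1.00,88.0,9.0,4.0,1.5,3.0,13.0,illustrative
bird_egg,Bird eggs,egg,other,3.00,25.0,48.0,39.9,4.0,0.0,0.0,illustrative
misc,Miscellaneous (unidentified),miscellaneous,other,,,,,,,,illustrative
"""


def builtin_reference() -> ReferenceTable:
    """Return the packaged illustrative reference table.

    Self-consistent (passes :func:`validate_reference`) and spanning all six
    primary categories; values are illustrative, not a study's measurements.
    """
    df_rows = pd.read_csv(io.StringIO(_BUILTIN_CSV), dtype={"ingredient_id": str})
    rows = []
    for rec in df_rows.to_dict("records"):
        row = {c: rec[c] for c in REFERENCE_COLUMNS}
        for num in ("cf", "dm_pct", "cp_pct", "ee_pct", "ash_pct", "cfiber_pct", "tdf_pct"):
            row[num] = None if pd.isna(row[num]) else float(row[num])
        rows.append(row)
    return _rows_to_table(rows, "builtin")


def write_reference(table: ReferenceTable, path: str | Path) -> None:
    """Write a reference table back out in the documented CSV schema."""
    table.to_frame().to_csv(path, index=False)
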