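"""Diet nutrient profiles on dry-matter and metabolizable-energy bases.

From a digestibility-corrected diet composition (EDC, % of ingested dry
matter, closed over identified ingredients) this module computes:

* the weighted nutrient profile, each nutrient a linear EDC-weighted sum of
  the per-ingredient concentrations (CP, EE, NfE, TDF, Ash, % DM);
* digestible carbohydrate (NfE) per ingredient by difference —
  ``100 - CP - EE - Ash - TDF`` for plant matter, but ``100 - CP - EE - Ash``
  for vertebrates, invertebrates and eggs, whose fiber fraction is
  proteinaceous (hair, tendon, chitin) and already counted inside CP;
* the metabolizable-energy (ME) basis via unmodified Atwater factors
  (16.72 kJ/g protein, 37.62 kJ/g fat, 16.72 kJ/g NfE); fiber and ash carry
  zero energy;
* two macronutrient ratios — protein:non-protein ``CP:(EE+NfE)`` and
  non-fat:fat ``(CP+NfE):EE`` — on both bases;
* the citric-acid-cycle minimum for the non-fat:fat ratio.  Beta-oxidation
  of fat requires oxaloacetate, which only glucogenic substrates (protein or
  carbohydrate) can supply; below a floor ratio the diet cannot sustain
  efficient aerobic combustion.  The floor is 3.55 on a DM basis; its ME
  counterpart is *derived*, not stored: because protein and NfE share one
  Atwater factor, the same diet sits at ``3.55 * 16.72 / 37.62 = 1.58`` on
  an ME basis.  A diet is below threshold on one basis iff on the other.

Undefined ratios (zero denominator) are ``None``, never infinity, so they
propagate as missing values in summaries instead of poisoning means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .edc import EdcVector
from .reference import IngredientDef, ReferenceTable


class DegenerateEnergyError(ValueError):
    """A diet with no energy-bearing nutrients has no ME basis."""


@dataclass(frozen=True)
class AtwaterFactors:
    """Metabolizable-energy coefficients, kJ per g of nutrient."""

    kj_per_g_protein: float = 16.72
    kj_per_g_fat: float = 37.62
    kj_per_g_nfe: float = 16.72

    def __post_init__(self):
        if min(self.kj_per_g_protein, self.kj_per_g_fat, self.kj_per_g_nfe) <= 0:
            raise ValueError("Atwater factors must be positive")


@dataclass(frozen=True)
class NutrientProfile:
    """Diet macronutrient concentrations on one basis.

    On the DM basis all five fields are % of ingested dry matter; TDF and
    ash are meaningful and ``cp+ee+nfe+tdf+ash`` equals 100 for plant-only
    diets (animal fiber overlaps CP, so mixed diets exceed 100 by exactly
    the EDC-weighted animal TDF).  On the ME basis cp/ee/nfe are % of
    metabolizable energy (closing to 100) and ``me_density`` is kJ per g DM.
    """

    basis: str  # "DM" | "ME"
    cp: float
    ee: float
    nfe: float
    tdf: float = 0.0
    ash: float = 0.0
    me_density: float | None = None


@dataclass(frozen=True)
class RatioSet:
    """The two macronutrient ratios on both bases, with threshold flags."""

    protein_ratio_dm: float | None
    protein_ratio_me: float | None
    nonfat_fat_dm: float | None
    nonfat_fat_me: float | None
    below_threshold_dm: bool | None = None
    below_threshold_me: bool | None = None


@dataclass(frozen=True)
class ThresholdSpec:
    """Minimum non-fat:fat ratio for efficient citric-acid-cycle function.

    Only the DM-basis floor is configured; the ME-basis floor is always
    derived through the Atwater factors (see :func:`me_threshold_from_dm`)
    so the two printed values cannot drift apart.
    """

    dm_min: float = 3.55
    atwater: AtwaterFactors = field(default_factory=AtwaterFactors)

    def __post_init__(self):
        if self.dm_min < 0:
            raise ValueError("dm_min must be >= 0")

    @property
    def me_min(self) -> float:
        return me_threshold_from_dm(self)


def ingredient_nfe(ing: IngredientDef) -> float:
    """Digestible carbohydrate (% DM) of one ingredient, by difference.

    Plants: ``100 - CP - EE - Ash - TDF`` (TDF, the more complete fiber
    measure, takes priority over crude fiber).  Animal matter (vertebrate,
    invertebrate, egg): ``100 - CP - EE - Ash`` — animal fiber is
    proteinaceous and already inside CP, so TDF is not subtracted again.
    """
    if ing.is_misc:
        raise ValueError(
            f"{ing.ingredient_id}: no nutrient composition can be attributed "
            "to miscellaneous matter"
        )
    base = 100.0 - ing.cp_pct - ing.ee_pct - ing.ash_pct
    if ing.kingdom == "plant":
        base -= ing.tdf_pct
    return base


def diet_nutrients_dm(edc: EdcVector, reference: ReferenceTable) -> NutrientProfile:
    """EDC-weighted diet nutrient profile on the dry-matter basis.

    ``edc`` must be closed over identified ingredients (miscellaneous
    removed and re-closed upstream); each nutrient is
    ``sum_i (EDC_i / 100) * nutrient_i`` and hence linear in EDC.
    """
    cp = ee = nfe = tdf = ash = 0.0
    for k, share in edc.values.items():
        ing = reference[k]
        if ing.is_misc:
            if share > 0:
                raise ValueError(
                    "EDC still contains a miscellaneous share; remove and "
                    "re-close before computing nutrients"
                )
            continue
        w = share / 100.0
        cp += w * ing.cp_pct
        ee += w * ing.ee_pct
        nfe += w * ingredient_nfe(ing)
        tdf += w * ing.tdf_pct
        ash += w * ing.ash_pct
    return NutrientProfile(basis="DM", cp=cp, ee=ee, nfe=nfe, tdf=tdf, ash=ash)


def to_me_basis(
    p: NutrientProfile, f: AtwaterFactors | None = None
) -> NutrientProfile:
    """Convert a DM-basis profile to percent-of-metabolizable-energy.

    Per 100 g DM the energy contributions are ``cp * 16.72``, ``ee * 37.62``
    and ``nfe * 16.72`` kJ; ME fractions are each share of the total, and
    ``me_density`` (kJ/g DM) is the total over 100.  Fiber and ash carry no
    energy and are not represented on this basis.
    """
    if p.basis != "DM":
        raise ValueError("to_me_basis expects a DM-basis profile")
    f = f or AtwaterFactors()
    e_cp = p.cp * f.kj_per_g_protein
    e_ee = p.ee * f.kj_per_g_fat
    e_nfe = p.nfe * f.kj_per_g_nfe
    total = e_cp + e_ee + e_nfe
    if total <= 0:
        raise DegenerateEnergyError("diet has zero metabolizable energy")
    return NutrientProfile(
        basis="ME",
        cp=100.0 * e_cp / total,
        ee=100.0 * e_ee / total,
        nfe=100.0 * e_nfe / total,
        me_density=total / 100.0,
    )


def protein_ratio(p: NutrientProfile) -> float | None:
    """Protein to non-protein ratio ``CP:(EE+NfE)``; ``None`` if undefined."""
    denom = p.ee + p.nfe
    if denom == 0:
        return None
    return p.cp / denom


def nonfat_fat_ratio(p: NutrientProfile) -> float | None:
    """Non-fat to fat ratio ``(CP+NfE):EE``; ``None`` if the diet has no fat."""
    if p.ee == 0:
        return None
    return (p.cp + p.nfe) / p.ee


def me_threshold_from_dm(
    spec: ThresholdSpec | None = None, f: AtwaterFactors | None = None
) -> float:
    """Derive the ME-basis non-fat:fat floor from the DM-basis floor.

    Moving from DM to ME multiplies the numerator (glucogenic mass) by the
    shared protein/NfE factor and the denominator (fat mass) by the fat
    factor, so the ratio scales by their quotient:
    ``me_min = dm_min * kj_nfe / kj_fat`` (defaults: 3.55 -> 1.58 to 2 dp).
    Requires equal protein and NfE factors; otherwise the conversion is not
    a single scalar and an error explains why.
    """
    spec = spec or ThresholdSpec()
    f = f or spec.atwater
    if f.kj_per_g_protein != f.kj_per_g_nfe:
        raise ValueError(
            "DM->ME threshold conversion assumes equal Atwater factors for "
            "protein and NfE; with unequal factors the ME floor depends on "
            "the protein/carbohydrate split and is not a single constant"
        )
    return spec.dm_min * f.kj_per_g_nfe / f.kj_per_g_fat


def compute_ratios(
    dm: NutrientProfile,
    me: NutrientProfile,
    spec: ThresholdSpec | None = None,
) -> RatioSet:
    """Assemble both ratios on both bases and apply the threshold flags."""
    r = RatioSet(
        protein_ratio_dm=protein_ratio(dm),
        protein_ratio_me=protein_ratio(me),
        nonfat_fat_dm=nonfat_fat_ratio(dm),
        nonfat_fat_me=nonfat_fat_ratio(me),
    )
    return flag_below_threshold(r, spec or ThresholdSpec())


def flag_below_threshold(r: RatioSet, spec: ThresholdSpec) -> RatioSet:
    """Set the below-threshold flags (strict ``<``; undefined stays ``None``)."""
    me_min = me_threshold_from_dm(spec)

    def flag(ratio, floor):
        return None if ratio is None else ratio < floor

    return RatioSet(
        protein_ratio_dm=r.protein_ratio_dm,
        protein_ratio_me=r.protein_ratio_me,
        nonfat_fat_dm=r.nonfat_fat_dm,
        nonfat_fat_me=r.nonfat_fat_me,
        below_threshold_dm=flag(r.nonfat_fat_dm, spec.dm_min),
        below_threshold_me=flag(r.nonfat_fat_me, me_min),
    )


def nutrient_table(
    scats,
    edc_vectors: dict[str, EdcVector],
    reference: ReferenceTable,
    *,
    atwater: AtwaterFactors | None = None,
    threshold: ThresholdSpec | None = None,
) -> pd.DataFrame:
    """Per-scat nutrient output table (full precision; round only for display).

    ``edc_vectors`` maps scat_id to the identified-only (misc-removed,
    re-closed) EDC of the scats that survived the miscellaneous filter.
    """
    atwater = atwater or AtwaterFactors()
    threshold = threshold or ThresholdSpec(atwater=atwater)
    rows = []
    for s in scats:
        if s.scat_id not in edc_vectors:
            continue
        dm = diet_nutrients_dm(edc_vectors[s.scat_id], reference)
        me = to_me_basis(dm, atwater)
        r = compute_ratios(dm, me, threshold)
        rows.append(
            {
                "scat_id": s.scat_id,
                "cp_dm": dm.cp,
                "ee_dm": dm.ee,
                "nfe_dm": dm.nfe,
                "tdf_dm": dm.tdf,
                "ash_dm": dm.ash,
                "cp_me": me.cp,
                "ee_me": me.ee,
                "nfe_me": me.nfe,
                "me_density_kj_g": me.me_density,
                "protein_ratio_dm": r.protein_ratio_dm,
                "protein_ratio_me": r.protein_ratio_me,
                "nonfat_fat_dm": r.nonfat_fat_dm,
                "nonfat_fat_me": r.nonfat_fat_me,
                "below_thr_dm": r.below_threshold_dm,
                "below_thr_me": r.below_threshold_me,
            }
        )
    return pd.DataFrame(rows)
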