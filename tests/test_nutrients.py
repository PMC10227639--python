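"""Nutrient profiles, Atwater conversion, ratios and the metabolic floor."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatdiet.edc import EdcVector
from scatdiet.nutrients import (
    AtwaterFactors,
    DegenerateEnergyError,
    NutrientProfile,
    RatioSet,
    ThresholdSpec,
    compute_ratios,
    diet_nutrients_dm,
    flag_below_threshold,
    ingredient_nfe,
    me_threshold_from_dm,
    nonfat_fat_ratio,
    protein_ratio,
    to_me_basis,
)
from scatdiet.reference import IngredientDef, ReferenceTable


def _plant(i, cp, ee, ash, tdf, cf=1.0):
    return IngredientDef(i, i, "plant", "fruit", cf, 10, cp, ee, ash, 0, tdf)


def _animal(i, kingdom, cp, ee, ash, tdf, cf=1.0):
    cat = "vertebrates" if kingdom == "vertebrate" else "insects"
    return IngredientDef(i, i, kingdom, cat, cf, 30, cp, ee, ash, 0, tdf)


@pytest.mark.parametrize(
    "ing,expected",
    [
        (_plant("p", 5, 3, 2, 30), 60.0),               # 100-5-3-2-30
        (_animal("v", "vertebrate", 55, 24, 15, 17), 6.0),  # TDF inside CP, ignored
        (_animal("i", "invertebrate", 60, 25, 15, 10), 0.0),
    ],
)
def test_ingredient_nfe_rules(ing, expected):
    assert ingredient_nfe(ing) == pytest.approx(expected)


def test_nfe_refuses_miscellaneous():
    misc = IngredientDef("m", "m", "miscellaneous", "other", None)
    with pytest.raises(ValueError, match="miscellaneous"):
        ingredient_nfe(misc)


def _table(*ings):
    d = {i.ingredient_id: i for i in ings}
    d["misc"] = IngredientDef("misc", "m", "miscellaneous", "other", None)
    return ReferenceTable(d)


def test_pure_diet_equals_ingredient_profile():
    t = _table(_plant("p", 5, 3, 2, 30))
    prof = diet_nutrients_dm(EdcVector({"p": 100.0}), t)
    assert (prof.cp, prof.ee, prof.nfe, prof.tdf, prof.ash) == (5, 3, 60, 30, 2)


def test_fifty_fifty_is_arithmetic_mean():
    t = _table(_plant("a", 10, 4, 2, 20), _plant("b", 30, 8, 6, 40))
    prof = diet_nutrients_dm(EdcVector({"a": 50.0, "b": 50.0}), t)
    assert prof.cp == pytest.approx(20)
    assert prof.ee == pytest.approx(6)
    assert prof.tdf == pytest.approx(30)
    assert prof.ash == pytest.approx(4)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(0, 1))
def test_linearity_in_edc_mixture(alpha):
    t = _table(_plant("a", 10, 4, 2, 20), _plant("b", 30, 8, 6, 40))
    mixed = diet_nutrients_dm(
        EdcVector({"a": 100 * alpha, "b": 100 * (1 - alpha)}), t
    )
    pa = diet_nutrients_dm(EdcVector({"a": 100.0}), t)
    pb = diet_nutrients_dm(EdcVector({"b": 100.0}), t)
    for f in ("cp", "ee", "nfe", "tdf", "ash"):
        assert getattr(mixed, f) == pytest.approx(
            alpha * getattr(pa, f) + (1 - alpha) * getattr(pb, f), abs=1e-9
        )


def test_plant_only_mass_balance_exact():
    t = _table(_plant("a", 10, 4, 2, 20), _plant("b", 30, 8, 6, 40))
    prof = diet_nutrients_dm(EdcVector({"a": 35.0, "b": 65.0}), t)
    assert prof.cp + prof.ee + prof.nfe + prof.tdf + prof.ash == pytest.approx(
        100.0, abs=1e-9
    )


def test_mixed_diet_exceeds_100_by_animal_tdf_overlap():
    t = _table(_plant("a", 10, 4, 2, 20), _animal("v", "vertebrate", 55, 20, 13, 12))
    edc = EdcVector({"a": 60.0, "v": 40.0})
    prof = diet_nutrients_dm(edc, t)
    overlap = 0.40 * 12  # animal TDF counted inside CP and again in TDF
    total = prof.cp + prof.ee + prof.nfe + prof.tdf + prof.ash
    assert total == pytest.approx(100.0 + overlap, abs=1e-9)


def test_nutrients_refuse_residual_misc():
    t = _table(_plant("a", 10, 4, 2, 20))
    with pytest.raises(ValueError, match="miscellaneous"):
        diet_nutrients_dm(EdcVector({"a": 96.0, "misc": 4.0}), t)


@pytest.mark.parametrize(
    "dm,expected_me",
    [
        ((0, 0, 100), (0, 0, 100)),
        ((50, 0, 50), (50, 0, 50)),  # protein and NfE share one factor
    ],
)
def test_me_conversion_simple_profiles(dm, expected_me):
    prof = NutrientProfile("DM", *dm)
    me = to_me_basis(prof)
    assert (me.cp, me.ee, me.nfe) == pytest.approx(expected_me)


def test_me_fat_fraction_uses_atwater_ratio():
    me = to_me_basis(NutrientProfile("DM", 0, 50, 50))
    assert me.ee == pytest.approx(100 * 37.62 / (37.62 + 16.72))
    assert me.ee == pytest.approx(69.23, abs=0.005)


def test_me_density_of_pure_carbohydrate():
    me = to_me_basis(NutrientProfile("DM", 0, 0, 100))
    assert me.me_density == pytest.approx(16.72)


def test_me_closure_and_degenerate_energy():
    me = to_me_basis(NutrientProfile("DM", 12, 5, 55, tdf=25, ash=3))
    assert me.cp + me.ee + me.nfe == pytest.approx(100, abs=1e-9)
    with pytest.raises(DegenerateEnergyError):
        to_me_basis(NutrientProfile("DM", 0, 0, 0, tdf=90, ash=10))


def test_protein_ratio_published_fall_optimum():
    # 17% of ME from protein, 83% from non-protein: the ~0.2 pre-hibernation ratio
    me = NutrientProfile("ME", cp=17, ee=10, nfe=73)
    assert protein_ratio(me) == pytest.approx(17 / 83)
    assert round(protein_ratio(me), 2) == 0.20


def test_ratio_sentinels():
    assert protein_ratio(NutrientProfile("DM", 0, 10, 40)) == 0
    assert protein_ratio(NutrientProfile("DM", 10, 0, 0)) is None
    assert nonfat_fat_ratio(NutrientProfile("DM", 10, 0, 40)) is None


def test_nonfat_fat_worked_example():
    assert nonfat_fat_ratio(NutrientProfile("DM", 30, 20, 41)) == pytest.approx(3.55)
    assert nonfat_fat_ratio(NutrientProfile("ME", 30, 60, 30)) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "dm_min,expected",
    [(3.55, 1.58), (0.0, 0.0), (37.62 / 16.72, 1.0)],
)
def test_me_threshold_derived_from_dm(dm_min, expected):
    got = me_threshold_from_dm(ThresholdSpec(dm_min=dm_min))
    assert round(got, 2) == pytest.approx(expected, abs=5e-3)


def test_threshold_conversion_needs_equal_glucogenic_factors():
    f = AtwaterFactors(kj_per_g_protein=17.0, kj_per_g_fat=37.62, kj_per_g_nfe=16.72)
    with pytest.raises(ValueError, match="equal Atwater"):
        me_threshold_from_dm(ThresholdSpec(dm_min=3.55, atwater=f))


@pytest.mark.parametrize(
    "ratio,below", [(3.55, False), (3.54, True), (None, None)]
)
def test_flag_below_threshold_strict(ratio, below):
    r = RatioSet(None, None, ratio, None)
    flagged = flag_below_threshold(r, ThresholdSpec())
    assert flagged.below_threshold_dm is below


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.floats(0.1, 90), st.floats(0.1, 90), st.floats(0.1, 90))
def test_me_ratio_identity_and_threshold_consistency(cp, ee, nfe):
    """cp_me = 100 r/(1+r); DM and ME threshold flags always agree."""
    total = cp + ee + nfe
    dm = NutrientProfile("DM", 100 * cp / total, 100 * ee / total, 100 * nfe / total)
    me = to_me_basis(dm)
    r = protein_ratio(me)
    assert me.cp == pytest.approx(100 * r / (1 + r), abs=1e-12 * 100)
    flags = compute_ratios(dm, me, ThresholdSpec())
    assert flags.below_threshold_dm == flags.below_threshold_me


def test_monotonic_cp_in_enriching_ingredient():
    t = _table(_plant("lo", 5, 4, 2, 20), _plant("hi", 40, 4, 2, 20))
    shares = [10, 30, 60, 90]
    cps = [
        diet_nutrients_dm(EdcVector({"hi": s, "lo": 100 - s}), t).cp for s in shares
    ]
    assert np.all(np.diff(cps) > 0)
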