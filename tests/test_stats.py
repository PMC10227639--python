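"""Stratified summaries, backward model selection and post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest

from scatdiet.stats import (
    ModelError,
    ModelSpec,
    fit_lmm_backward,
    posthoc_pairwise,
    residual_diagnostics,
    season_deltas,
    stratified_summary,
)

CLASSES = ["lone_female", "adult_male", "subadult_female"]


def _simulated_frame(
    rng,
    n_bears=24,
    scats_per_bear=10,
    season_effect=0.0,
    class_effects=None,
    bear_sd=0.5,
):
    rows = []
    for b in range(n_bears):
        u = rng.normal(0, bear_sd)
        cls = CLASSES[b % len(CLASSES)]
        for j in range(scats_per_bear):
            season = "summer" if j % 2 == 0 else "fall"
            year = 2017 + (j // (scats_per_bear // 2 or 1)) % 2
            y = u + rng.normal()
            if season == "fall":
                y += season_effect
            if class_effects:
                y += class_effects.get(cls, 0.0)
            rows.append(
                dict(
                    bear_id=f"b{b:02d}",
                    season=season,
                    year=year,
                    reproductive_class=cls,
                    y=y,
                )
            )
    return pd.DataFrame(rows)


def test_stratified_summary_mean_sd_n():
    df = pd.DataFrame(
        {
            "season": ["fall", "fall", "summer"],
            "cp_dm": [10.0, 30.0, 12.0],
            "stats_eligible": [True, True, True],
        }
    )
    out = stratified_summary(df, ["season"], ["cp_dm"])
    fall = out[out["season"] == "fall"].iloc[0]
    assert fall["mean"] == pytest.approx(20.0)
    assert fall["sd"] == pytest.approx(np.sqrt(200), abs=1e-9)  # n-1 denominator
    assert fall["n"] == 2
    summer = out[out["season"] == "summer"].iloc[0]
    assert summer["n"] == 1 and np.isnan(summer["sd"])


def test_summary_excludes_ineligible_by_default():
    df = pd.DataFrame(
        {
            "season": ["spring", "fall"],
            "cp_dm": [40.0, 10.0],
            "stats_eligible": [False, True],
        }
    )
    strict = stratified_summary(df, ["season"], ["cp_dm"])
    assert set(strict["season"]) == {"fall"}
    descriptive = stratified_summary(df, ["season"], ["cp_dm"], stats_eligible_only=False)
    assert set(descriptive["season"]) == {"spring", "fall"}


def test_summary_invariant_to_row_order_and_bear_labels():
    rng = np.random.default_rng(0)
    df = _simulated_frame(rng, n_bears=6, scats_per_bear=4)
    df["stats_eligible"] = True
    a = stratified_summary(df, ["season"], ["y"])
    shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
    shuffled["bear_id"] = shuffled["bear_id"].map(lambda s: "relab_" + s)
    b = stratified_summary(shuffled, ["season"], ["y"])
    pd.testing.assert_frame_equal(
        a.sort_values("season").reset_index(drop=True),
        b.sort_values("season").reset_index(drop=True),
    )


def test_season_deltas():
    summ = pd.DataFrame(
        {
            "season": ["summer", "fall"],
            "variable": ["cp_dm", "cp_dm"],
            "mean": [38.0, 12.2],
            "sd": [21.8, 11.8],
            "n": [100, 100],
        }
    )
    out = season_deltas(summ)
    assert out["delta_summer_minus_fall"].iloc[0] == pytest.approx(25.8)


def test_single_bear_is_an_error():
    df = pd.DataFrame(
        dict(bear_id=["b0"] * 6, season=["summer", "fall"] * 3,
             year=[2017] * 6, reproductive_class=["lone_female"] * 6,
             y=np.arange(6.0))
    )
    with pytest.raises(ModelError, match="2"):
        fit_lmm_backward(ModelSpec(response="y"), df)


def test_strong_season_effect_is_retained_and_significant():
    rng = np.random.default_rng(21)
    df = _simulated_frame(rng, season_effect=2.0)
    fit = fit_lmm_backward(ModelSpec(response="y"), df)
    assert "season" in fit.retained_main
    contrasts = posthoc_pairwise(fit, "season")
    assert len(contrasts) == 1  # 2 levels -> a single contrast
    assert contrasts["p_tukey"].iloc[0] < 0.05
    assert contrasts["estimate"].iloc[0] == pytest.approx(2.0, abs=0.5)


def test_marginality_no_interaction_without_main_effects():
    rng = np.random.default_rng(5)
    df = _simulated_frame(rng, season_effect=1.5,
                          class_effects={"adult_male": 1.5})
    fit = fit_lmm_backward(ModelSpec(response="y"), df)
    for a, b in fit.retained_interactions:
        assert a in fit.retained_main and b in fit.retained_main
    dropped = [e for e in fit.elimination_log if e["action"] == "dropped"]
    assert all(e["p"] > fit.spec.alpha for e in dropped)


def test_tukey_with_two_levels_equals_unadjusted_t():
    from scipy import stats as sps

    rng = np.random.default_rng(3)
    df = _simulated_frame(rng, season_effect=1.0)
    fit = fit_lmm_backward(ModelSpec(response="y"), df)
    row = posthoc_pairwise(fit, "season").iloc[0]
    p_t = 2 * sps.t.sf(abs(row["t_ratio"]), row["df"])
    assert row["p_tukey"] == pytest.approx(p_t, rel=1e-3)


def test_posthoc_contrast_count_is_k_choose_2():
    rng = np.random.default_rng(8)
    df = _simulated_frame(
        rng, class_effects={"adult_male": 3.0, "subadult_female": -3.0}
    )
    fit = fit_lmm_backward(
        ModelSpec(response="y", include_interactions=False), df
    )
    assert "reproductive_class" in fit.retained_main
    contrasts = posthoc_pairwise(fit, "reproductive_class")
    k = df["reproductive_class"].nunique()
    assert len(contrasts) == k * (k - 1) // 2
    am_sf = contrasts[contrasts["contrast"] == "adult_male - subadult_female"]
    assert am_sf["p_tukey"].iloc[0] < 0.05
    assert am_sf["estimate"].iloc[0] == pytest.approx(6.0, abs=1.5)


def test_posthoc_requires_retained_factor():
    rng = np.random.default_rng(9)
    df = _simulated_frame(rng, season_effect=2.0)
    fit = fit_lmm_backward(ModelSpec(response="y"), df)
    with pytest.raises(ModelError, match="year"):
        posthoc_pairwise(fit, "year")


def test_diagnostics_normal_residuals_pass_w_threshold():
    rng = np.random.default_rng(12)
    df = _simulated_frame(rng, n_bears=20, scats_per_bear=10, season_effect=1.0)
    fit = fit_lmm_backward(ModelSpec(response="y"), df)
    diag = residual_diagnostics(fit, seed=0)
    assert diag["shapiro_w"] >= 0.95
    assert set(diag["table"].columns) == {"fitted", "std_residual"}
    assert len(diag["table"]) == len(df)


def test_diagnostics_flag_heavy_tails():
    # Cauchy noise: W should fall well under the 0.95 normality bar.
    rng = np.random.default_rng(13)
    df = _simulated_frame(rng, n_bears=20, scats_per_bear=10, bear_sd=0.0)
    df["y"] = rng.standard_t(1, size=len(df))
    fit = fit_lmm_backward(
        ModelSpec(response="y", include_interactions=False), df
    )
    assert residual_diagnostics(fit, seed=0)["shapiro_w"] < 0.95


def test_diagnostics_constant_residuals_degenerate():
    df = pd.DataFrame(
        dict(bear_id=[f"b{i%4}" for i in range(12)],
             season=["summer", "fall"] * 6,
             year=[2017] * 12, reproductive_class=["lone_female"] * 12,
             y=[1.0] * 12)
    )
    # degenerate input errors at fit time or, if a fit limps through, at
    # the diagnostics stage — never silently yields a W statistic
    with pytest.raises(ModelError):
        fit = fit_lmm_backward(
            ModelSpec(response="y", include_interactions=False), df
        )
        residual_diagnostics(fit)
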