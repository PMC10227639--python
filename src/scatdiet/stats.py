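"""Stratified summaries and mixed-model inference for the compiled dataset.

The analysis design mirrors standard practice for repeated scat samples
from marked individuals: every response (category EDC shares, nutrient
concentrations on either basis, nutrient ratios) is modelled with a linear
mixed model with a random intercept per bear — scats from the same bear are
not independent — and fixed effects chosen by backward stepwise elimination
from {year, season, reproductive class} and all their two-way interactions,
keeping only terms significant at alpha <= 0.05.  Elimination respects
marginality: an interaction is always removed before either of its main
effects, and a main effect is never dropped while an interaction containing
it is retained.  Selection uses likelihood-ratio tests between nested
maximum-likelihood fits; the reported model is refit by REML.

Post-hoc pairwise comparisons of a retained factor use estimated marginal
means (averaging predictions over a balanced grid of the other retained
factors) with Tukey adjustment through the studentized range distribution.
Denominator degrees of freedom default to the residual approximation
``n - rank(X)``; a containment-style option subtracts the group count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf

ALPHA_DEFAULT = 0.05

FACTOR_COLUMNS = ("year", "season", "reproductive_class")


class ModelError(ValueError):
    pass


def stratified_summary(
    data: pd.DataFrame,
    keys: list[str],
    variables: list[str],
    *,
    stats_eligible_only: bool = True,
) -> pd.DataFrame:
    """Group mean, sample SD (n-1 denominator) and n per stratum.

    One row per (stratum x variable).  Cells with a single scat report the
    mean with SD missing; empty groups simply do not appear (a full grid can
    be reindexed downstream).  Spring and out-of-season scats are excluded
    unless ``stats_eligible_only=False`` (descriptive tables may include
    them).
    """
    df = data
    if stats_eligible_only and "stats_eligible" in df.columns:
        df = df[df["stats_eligible"]]
    if df.empty:
        return pd.DataFrame(columns=[*keys, "variable", "mean", "sd", "n"])
    rows = []
    for group_vals, grp in df.groupby(keys, sort=True, observed=True, dropna=False):
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        for var in variables:
            x = grp[var].dropna().astype(float)
            rows.append(
                {
                    **dict(zip(keys, group_vals)),
                    "variable": var,
                    "mean": x.mean() if len(x) else np.nan,
                    "sd": x.std(ddof=1) if len(x) >= 2 else np.nan,
                    "n": int(len(x)),
                }
            )
    return pd.DataFrame(rows)


def season_deltas(summary: pd.DataFrame, pair=("summer", "fall")) -> pd.DataFrame:
    """Mean differences between two named seasons for each remaining stratum."""
    a, b = pair
    piv = summary.pivot_table(
        index=[c for c in summary.columns if c not in ("season", "mean", "sd", "n")],
        columns="season",
        values="mean",
        observed=True,
    )
    if a not in piv.columns or b not in piv.columns:
        return pd.DataFrame()
    out = piv[[a, b]].copy()
    out[f"delta_{a}_minus_{b}"] = out[a] - out[b]
    return out.reset_index()


@dataclass(frozen=True)
class ModelSpec:
    """Response plus the candidate fixed-effect structure."""

    response: str
    candidate_factors: tuple[str, ...] = FACTOR_COLUMNS
    include_interactions: bool = True
    group: str = "bear_id"
    alpha: float = ALPHA_DEFAULT


@dataclass
class FittedLMM:
    """Backward-selection outcome: final REML fit plus the audit trail."""

    spec: ModelSpec
    result: object  # statsmodels MixedLMResults (REML refit)
    retained_main: list[str]
    retained_interactions: list[tuple[str, str]]
    elimination_log: list[dict] = field(default_factory=list)
    data: pd.DataFrame | None = None

    @property
    def retained_terms(self) -> list[str]:
        return self.retained_main + [f"{a}:{b}" for a, b in self.retained_interactions]


def _term_formula(factor: str) -> str:
    return f"C({factor})"


def _build_formula(response: str, mains: list[str], inters: list[tuple[str, str]]) -> str:
    parts = [_term_formula(m) for m in mains]
    parts += [f"{_term_formula(a)}:{_term_formula(b)}" for a, b in inters]
    rhs = " + ".join(parts) if parts else "1"
    return f"{response} ~ {rhs}"


def _fit(formula: str, data: pd.DataFrame, group: str, reml: bool):
    # lbfgs can land on a boundary where the Hessian is singular; fall back
    # through derivative-free optimizers before giving up.
    model = smf.mixedlm(formula, data=data, groups=data[group])
    last_exc = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method)
            if np.isfinite(res.llf) and np.all(np.isfinite(res.fe_params)):
                return res
            last_exc = ModelError(f"non-finite fit via {method}")
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise ModelError(f"mixed model failed to converge for {formula!r}: {last_exc}")


def _fit_ml(formula: str, data: pd.DataFrame, group: str):
    return _fit(formula, data, group, reml=False)


def _lr_pvalue(full, reduced) -> float:
    lr = 2.0 * (full.llf - reduced.llf)
    df = full.model.k_fe - reduced.model.k_fe
    if df <= 0:
        return 1.0
    return float(sps.chi2.sf(max(lr, 0.0), df))


def fit_lmm_backward(spec: ModelSpec, data: pd.DataFrame) -> FittedLMM:
    """Backward stepwise elimination to the minimal adequate mixed model.

    Starting from all candidate main effects (and, optionally, all two-way
    interactions), repeatedly drops the least significant *droppable* term —
    interactions first; a main effect only once no retained interaction
    contains it — whenever its likelihood-ratio p-value exceeds alpha.
    Factors with a single observed level are excluded from the candidate set
    up front.  Raises :class:`ModelError` with fewer than two bears.
    """
    df = data.dropna(subset=[spec.response]).copy()
    if "stats_eligible" in df.columns:
        df = df[df["stats_eligible"]]
    if df[spec.group].nunique() < 2:
        raise ModelError(
            f"need >= 2 groups ({spec.group}) for a random intercept; "
            f"got {df[spec.group].nunique()}"
        )
    mains = [f for f in spec.candidate_factors if df[f].nunique() >= 2]
    inters = (
        [tuple(c) for c in itertools.combinations(mains, 2)]
        if spec.include_interactions
        else []
    )
    log: list[dict] = []
    step = 0
    current = _fit_ml(_build_formula(spec.response, mains, inters), df, spec.group)
    while True:
        droppable: list[tuple[str, list, list]] = []
        for pair in inters:
            droppable.append(
                (f"{pair[0]}:{pair[1]}", mains, [i for i in inters if i != pair])
            )
        in_inter = {f for pair in inters for f in pair}
        for m in mains:
            if m not in in_inter:
                droppable.append((m, [x for x in mains if x != m], inters))
        if not droppable:
            break
        best = None
        for label, new_mains, new_inters in droppable:
            reduced = _fit_ml(
                _build_formula(spec.response, new_mains, new_inters), df, spec.group
            )
            p = _lr_pvalue(current, reduced)
            if best is None or p > best[0]:
                best = (p, label, new_mains, new_inters, reduced)
        p, label, new_mains, new_inters, reduced = best
        step += 1
        if p > spec.alpha:
            log.append({"step": step, "term": label, "p": p, "action": "dropped"})
            mains, inters, current = list(new_mains), list(new_inters), reduced
        else:
            log.append({"step": step, "term": label, "p": p, "action": "stopped"})
            break

    final_formula = _build_formula(spec.response, mains, inters)
    result = _fit(final_formula, df, spec.group, reml=True)
    return FittedLMM(
        spec=spec,
        result=result,
        retained_main=mains,
        retained_interactions=inters,
        elimination_log=log,
        data=df,
    )


def _residual_df(fit: FittedLMM, method: str) -> float:
    res = fit.result
    n = res.model.exog.shape[0]
    p = np.linalg.matrix_rank(res.model.exog)
    if method == "residual":
        return float(n - p)
    if method == "containment":
        k = fit.data[fit.spec.group].nunique()
        return float(max(n - p - (k - 1), 1))
    raise ValueError(f"unknown df method {method!r}")


def posthoc_pairwise(
    fit: FittedLMM, factor: str, *, df_method: str = "residual"
) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of a retained factor's marginal means.

    Marginal means average model predictions over a balanced grid of the
    other retained factors (each observed level weighted equally).  The
    adjusted p-value is ``P(Q_{k,df} >= |t| * sqrt(2))`` with Q the
    studentized range over the factor's k levels; for k = 2 this equals the
    unadjusted two-sided t test.
    """
    if factor not in fit.retained_main:
        raise ModelError(f"factor {factor!r} is not in the selected model")
    df = fit.data
    res = fit.result
    design_info = res.model.data.design_info
    levels = sorted(df[factor].dropna().unique().tolist())
    others = [f for f in fit.retained_main if f != factor]
    other_levels = [sorted(df[f].dropna().unique().tolist()) for f in others]

    def emm_row(level) -> np.ndarray:
        grid = [
            {factor: level, **dict(zip(others, combo))}
            for combo in itertools.product(*other_levels)
        ] or [{factor: level}]
        gdf = pd.DataFrame(grid)
        X = np.asarray(patsy.build_design_matrices([design_info], gdf)[0])
        return X.mean(axis=0)

    L = {lv: emm_row(lv) for lv in levels}
    fe = res.fe_params.values
    cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
    k = len(levels)
    ddf = _residual_df(fit, df_method)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        d = L[a] - L[b]
        est = float(d @ fe)
        se = float(np.sqrt(d @ cov @ d))
        t = est / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, ddf))
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "df": ddf,
                "t_ratio": t,
                "p_tukey": min(max(p, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


#: Largest sample passed to the Shapiro-Wilk statistic before seeded
#: subsampling kicks in (the W approximation degrades for huge n).
SHAPIRO_MAX_N = 4500


def residual_diagnostics(fit: FittedLMM, *, seed: int = 0) -> dict:
    """Shapiro-Wilk W on model residuals plus a fitted-vs-residual export.

    Returns ``{"shapiro_w", "shapiro_p", "subsampled", "table"}`` where the
    table holds fitted values and standardized residuals for a homogeneity
    plot.  Residuals with zero variance are degenerate input.
    """
    resid = np.asarray(fit.result.resid, dtype=float)
    resid = resid[np.isfinite(resid)]
    if resid.size < 3 or np.std(resid) == 0:
        raise ModelError("residuals are constant or too few for diagnostics")
    sample = resid
    subsampled = False
    if resid.size > SHAPIRO_MAX_N:
        rng = np.random.default_rng(seed)
        sample = rng.choice(resid, SHAPIRO_MAX_N, replace=False)
        subsampled = True
    w, p = sps.shapiro(sample)
    fitted = np.asarray(fit.result.fittedvalues, dtype=float)
    std_resid = (resid - resid.mean()) / resid.std(ddof=1)
    table = pd.DataFrame({"fitted": fitted, "std_residual": std_resid})
    return {
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "subsampled": subsampled,
        "table": table,
    }
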