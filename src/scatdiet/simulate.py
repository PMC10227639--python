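"""Synthetic scat datasets with known ground truth.

Generates download-free datasets shaped like a multi-year Scandinavian
brown bear scat collection: a roster of bears with reproductive classes, a
per-scat *true* ingested diet (EDC, % DM), and the fecal volume vectors a
field team would have recorded, produced by the exact algebraic inverse of
the correction-factor transform:

    Vf_i = 100 * (EDC_i / CF_i) / sum_j (EDC_j / CF_j)

so that running the pipeline on a noise-free synthetic dataset recovers the
truth to numerical precision.  Optional multinomial resampling of Vf
emulates visual subsample estimation error.

Diet mixtures are drawn hierarchically: per (season, reproductive class) a
Dirichlet over the six primary categories, then a nested Dirichlet over the
ingredients within each category, with a per-bear random intercept on the
logit of the fruit share to create the within-bear correlation that the
mixed-model random effect targets.  The ``study_shape`` preset emulates the
published seasonal pattern of this system — vertebrate- and ant-heavy
summers, berry-dominated falls, a berry-failure year in 2015 that pushed
summer diets toward ants, and a strong oat signal in the fall diet of adult
males — at the published scale (~55 bears, ~886 scats over 2015-2018).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import BearMeta, ScatRecord, SeasonCalendar, SEASONS
from .reference import CATEGORIES, ReferenceTable, builtin_reference, write_reference

# Category-level Dirichlet concentrations per season.  Means follow the
# published seasonal category shares (fall: fruit-dominated with an
# anthropogenic tail; summer: insects/vertebrates/vegetation-heavy); the
# small totals (~1.5-2) give the large between-scat spread real scat data
# shows, with many scats close to a single category.
_SEASON_ALPHA = {
    "spring": {
        "fruit": 0.225,
        "insects": 0.18,
        "vertebrates": 0.525,
        "natural_vegetation": 0.525,
        "anthropogenic_vegetation": 0.03,
        "other": 0.015,
    },
    "summer": {
        "fruit": 0.446,
        "insects": 0.602,
        "vertebrates": 0.420,
        "natural_vegetation": 0.430,
        "anthropogenic_vegetation": 0.090,
        "other": 0.012,
    },
    "fall": {
        "fruit": 1.056,
        "insects": 0.084,
        "vertebrates": 0.0525,
        "natural_vegetation": 0.090,
        "anthropogenic_vegetation": 0.213,
        "other": 0.0045,
    },
}

# Within-category ingredient splits (Dirichlet concentrations).  Eggs are
# given zero weight in the presets: the "other" category of a typical scat
# is unidentifiable matter, and egg-dominated scats are rare outliers.
_WITHIN_ALPHA = {
    "fruit": {"bilberry": 3.0, "lingonberry": 1.5, "crowberry": 0.8},
    "insects": {"formica": 4.0, "wasp": 0.6},
    "vertebrates": {"moose": 3.0, "small_mammal": 0.8, "bear_hair": 0.3},
    "natural_vegetation": {"graminoid": 2.0, "forb": 1.5, "mushroom": 0.4},
    "anthropogenic_vegetation": {"oats": 3.0, "maize": 0.5},
    "other": {"misc": 1.0},
}

# Multiplicative tweaks to category concentrations per (reproductive class,
# season).  Adult males substitute oats for berries in fall; females with
# cubs of the year avoid carcass sites; subadults eat more ants.
_CLASS_EFFECTS = {
    ("adult_male", "fall"): {"anthropogenic_vegetation": 3.5, "fruit": 0.7},
    ("female_with_coy", None): {"vertebrates": 0.4},
    ("subadult_female", None): {"fruit": 1.3},
    ("subadult_male", None): {"insects": 1.3},
}

#: In a berry-failure year the summer fruit signal collapses and ants fill in.
_BERRY_FAILURE_SUMMER = {"fruit": 0.25, "insects": 1.6}

_DEFAULT_CLASS_DIST = {
    "lone_female": 0.25,
    "adult_male": 0.11,
    "female_with_yearlings": 0.15,
    "female_with_coy": 0.15,
    "subadult_female": 0.17,
    "subadult_male": 0.17,
}


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; one seed drives all randomness."""

    n_bears: int = 55
    years: tuple[int, ...] = (2015, 2016, 2017, 2018)
    scats_per_bear_per_season: dict = field(
        default_factory=lambda: {"spring": 1, "summer": 3, "fall": 4}
    )
    class_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_DIST))
    berry_failure_years: tuple[int, ...] = ()
    bear_active_prob: float = 1.0
    bear_sigma: float = 0.4  # SD of the per-bear logit-fruit intercept
    noise_draws: int | None = None  # multinomial Vf resampling; None = exact
    accompanied_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_bears < 0:
            raise ValueError("n_bears must be >= 0")
        if not self.years:
            raise ValueError("need at least one year")
        probs = np.array(list(self.class_distribution.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_distribution must be a probability vector")
        if not 0 <= self.bear_active_prob <= 1:
            raise ValueError("bear_active_prob must be in [0, 1]")
        if self.noise_draws is not None and self.noise_draws < 1:
            raise ValueError("noise_draws must be >= 1")


def study_shape_config(seed: int = 0) -> SimConfig:
    """Preset at the published study's scale and seasonal structure."""
    return SimConfig(
        n_bears=55,
        years=(2015, 2016, 2017, 2018),
        berry_failure_years=(2015,),
        bear_active_prob=0.53,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground truth: per-scat true ingested EDC plus the labels behind it."""

    scat_ids: list[str]
    bear_ids: list[str]
    dates: list[dt.date]
    seasons: list[str]
    years: list[int]
    classes: list[str]
    true_edc: pd.DataFrame  # rows = scats, columns = ingredient ids, rows sum to 100
    bear_intercepts: dict[str, float]


def simulate_population(config: SimConfig) -> dict[str, BearMeta]:
    """Draw the bear roster; deterministic under the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_distribution)
    probs = np.array([config.class_distribution[c] for c in classes], dtype=float)
    bears: dict[str, BearMeta] = {}
    for i in range(config.n_bears):
        bid = f"W{i + 1:04d}"
        cls = classes[rng.choice(len(classes), p=probs)]
        accompanied = (
            cls.startswith("subadult") and rng.random() < config.accompanied_fraction
        )
        bears[bid] = _meta_for_class(bid, cls, rng, accompanied)
    return bears


def _meta_for_class(bid: str, cls: str, rng, accompanied: bool) -> BearMeta:
    if cls.startswith("subadult"):
        sex = "F" if cls == "subadult_female" else "M"
        age = int(rng.integers(1, 4))
        group = "subadult"
        coy = yearlings = False
    else:
        sex = "M" if cls == "adult_male" else "F"
        age = int(rng.integers(4, 16))
        group = "adult"
        coy = cls == "female_with_coy"
        yearlings = cls == "female_with_yearlings"
    return BearMeta(
        bear_id=bid,
        sex=sex,
        age=age,
        age_group=group,
        reproductive_class=cls,
        accompanied_by_mother=accompanied,
        with_coy=coy,
        with_yearlings=yearlings,
    )


def _category_alpha(season: str, cls: str, year: int, config: SimConfig) -> np.ndarray:
    alpha = dict(_SEASON_ALPHA[season])
    if season == "summer" and year in config.berry_failure_years:
        for cat, f in _BERRY_FAILURE_SUMMER.items():
            alpha[cat] *= f
    for (eff_cls, eff_season), tweaks in _CLASS_EFFECTS.items():
        if eff_cls == cls and eff_season in (None, season):
            for cat, f in tweaks.items():
                alpha[cat] *= f
    return np.array([alpha[c] for c in CATEGORIES], dtype=float)


def _logit_tilt(shares: np.ndarray, idx: int, u: float) -> np.ndarray:
    """Shift share ``idx`` by ``u`` on the logit scale; rescale the rest."""
    p = shares[idx]
    if p <= 0.0 or p >= 1.0 or u == 0.0:
        return shares
    z = np.log(p / (1 - p)) + u
    q = 1.0 / (1.0 + np.exp(-z))
    out = shares * (1 - q) / (1 - p)
    out[idx] = q
    return out


def simulate_true_diets(
    bears: dict[str, BearMeta],
    config: SimConfig,
    reference: ReferenceTable | None = None,
) -> SyntheticTruth:
    """Draw per-scat true ingested diets (EDC % DM) for the roster."""
    config.validate()
    reference = reference or builtin_reference()
    rng = np.random.default_rng((config.seed, 1))
    cal = SeasonCalendar()
    fruit_idx = CATEGORIES.index("fruit")
    ing_ids = reference.ids
    col_index = {k: j for j, k in enumerate(ing_ids)}

    intercepts = {
        bid: float(rng.normal(0.0, config.bear_sigma)) for bid in sorted(bears)
    }

    scat_ids, bear_ids, dates, seasons, years, classes = [], [], [], [], [], []
    rows = []
    n = 0
    for year in config.years:
        for bid in sorted(bears):
            if rng.random() >= config.bear_active_prob:
                continue
            cls = bears[bid].reproductive_class
            for season in SEASONS:
                k = config.scats_per_bear_per_season.get(season, 0)
                for _ in range(k):
                    n += 1
                    alpha = _category_alpha(season, cls, year, config)
                    cat_shares = rng.dirichlet(alpha)
                    cat_shares = _logit_tilt(cat_shares, fruit_idx, intercepts[bid])
                    vec = np.zeros(len(ing_ids))
                    for ci, cat in enumerate(CATEGORIES):
                        if cat_shares[ci] <= 0:
                            continue
                        within = _WITHIN_ALPHA[cat]
                        names = list(within)
                        w = rng.dirichlet(np.array([within[x] for x in names]))
                        for name, share in zip(names, w):
                            vec[col_index[name]] += 100.0 * cat_shares[ci] * share
                    scat_ids.append(f"S{n:05d}")
                    bear_ids.append(bid)
                    dates.append(_random_date(rng, year, season, cal))
                    seasons.append(season)
                    years.append(year)
                    classes.append(cls)
                    rows.append(vec)
    true_edc = pd.DataFrame(rows, index=scat_ids, columns=ing_ids)
    return SyntheticTruth(
        scat_ids=scat_ids,
        bear_ids=bear_ids,
        dates=dates,
        seasons=seasons,
        years=years,
        classes=classes,
        true_edc=true_edc,
        bear_intercepts=intercepts,
    )


def _random_date(rng, year: int, season: str, cal: SeasonCalendar) -> dt.date:
    if season == "spring":
        start, end = cal.spring_start_for(year), cal._d(year, cal.spring_end)
    elif season == "summer":
        start, end = cal._d(year, cal.summer_start), cal._d(year, cal.summer_end)
    else:
        start, end = cal._d(year, cal.fall_start), cal._d(year, cal.fall_end)
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def forward_fecal_volumes(
    true_edc: dict[str, float] | pd.Series,
    reference: ReferenceTable,
) -> dict[str, float]:
    """Exact forward model: true ingested EDC -> fecal volume percentages.

    Inverts the correction-factor transform: ``Vf_i`` is proportional to
    ``EDC_i / CF_i``, closed to 100.  Miscellaneous matter uses the mean CF
    of the identified ingredients present in the same scat — the same
    convention the inverse direction applies — so the round trip through
    :func:`scatdiet.edc.compute_edc` is exact.
    """
    items = dict(true_edc)
    if sum(items.values()) <= 0:
        raise ValueError("true EDC is all zero")
    misc_id = reference.misc_id
    present_identified = [k for k, v in items.items() if v > 0 and k != misc_id]
    misc_cf = None
    if misc_id in items and items.get(misc_id, 0) > 0:
        if not present_identified:
            raise ValueError("scat is pure miscellaneous; forward model undefined")
        misc_cf = float(np.mean([reference[k].cf for k in present_identified]))

    def cf_of(k):
        return misc_cf if k == misc_id else reference[k].cf

    w = {k: (v / cf_of(k) if v > 0 else 0.0) for k, v in items.items()}
    denom = sum(w.values())
    return {k: 100.0 * x / denom for k, x in w.items()}


def _apply_noise(vf: dict[str, float], rng, n_draws: int) -> dict[str, float]:
    keys = list(vf)
    p = np.array([vf[k] for k in keys], dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(n_draws, p)
    return {k: 100.0 * c / n_draws for k, c in zip(keys, counts)}


def truth_to_scats(
    truth: SyntheticTruth,
    config: SimConfig,
    reference: ReferenceTable | None = None,
) -> list[ScatRecord]:
    """Materialize observable scat records from the truth table."""
    reference = reference or builtin_reference()
    rng = np.random.default_rng((config.seed, 2))
    records = []
    for i, sid in enumerate(truth.scat_ids):
        vf = forward_fecal_volumes(truth.true_edc.loc[sid], reference)
        if config.noise_draws is not None:
            vf = _apply_noise(vf, rng, config.noise_draws)
            total = sum(vf.values())
            vf = {k: v * 100.0 / total for k, v in vf.items()}
        records.append(
            ScatRecord(
                scat_id=sid,
                bear_id=truth.bear_ids[i],
                date=truth.dates[i],
                weight_g=float(np.round(rng.gamma(8.0, 40.0), 1)),
                volume_ml=float(np.round(rng.gamma(8.0, 35.0), 1)),
                vf=vf,
            )
        )
    return records


def simulate_dataset(
    config: SimConfig, reference: ReferenceTable | None = None
) -> tuple[dict[str, BearMeta], SyntheticTruth, list[ScatRecord]]:
    """Roster + truth + observable scats in one call."""
    reference = reference or builtin_reference()
    bears = simulate_population(config)
    truth = simulate_true_diets(bears, config, reference)
    scats = truth_to_scats(truth, config, reference)
    return bears, truth, scats


def write_dataset(
    truth: SyntheticTruth,
    bears: dict[str, BearMeta],
    config: SimConfig,
    out_dir: str | Path,
    reference: ReferenceTable | None = None,
) -> dict[str, Path]:
    """Write scats/bears/truth/reference CSVs in the documented schemas.

    The truth table goes to its own file so the pipeline cannot "see" it.
    Every file starts with a comment line embedding the generator seed.
    """
    reference = reference or builtin_reference()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# scatdiet synthetic dataset, seed={config.seed}\n"
    scats = truth_to_scats(truth, config, reference)

    scat_rows = []
    for s in scats:
        row = {
            "scat_id": s.scat_id,
            "bear_id": s.bear_id,
            "date": s.date.isoformat(),
            "weight_g": s.weight_g,
            "volume_ml": s.volume_ml,
        }
        row.update({f"vf_{k}": v for k, v in s.vf.items()})
        scat_rows.append(row)
    paths = {
        "scats": out / "scats.csv",
        "bears": out / "bears.csv",
        "truth": out / "truth.csv",
        "reference": out / "reference.csv",
    }
    _write_csv(pd.DataFrame(scat_rows), paths["scats"], header)

    bear_rows = [
        {
            "bear_id": b.bear_id,
            "sex": b.sex,
            "age": b.age,
            "age_group": b.age_group,
            "reproductive_class": b.reproductive_class,
            "accompanied_by_mother": b.accompanied_by_mother,
            "with_coy": b.with_coy,
            "with_yearlings": b.with_yearlings,
        }
        for b in bears.values()
    ]
    _write_csv(pd.DataFrame(bear_rows), paths["bears"], header)

    truth_long = (
        truth.true_edc.rename_axis("scat_id")
        .reset_index()
        .melt(id_vars="scat_id", var_name="ingredient_id", value_name="true_edc_pct")
    )
    truth_long = truth_long[truth_long["true_edc_pct"] > 0]
    _write_csv(truth_long, paths["truth"], header)

    write_reference(reference, paths["reference"])
    return paths


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
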