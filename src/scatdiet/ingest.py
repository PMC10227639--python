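"""Scat and bear-metadata ingest: schemas, seasons, reproductive classes.

Reads the two delimited inputs of a scat-based diet study — per-scat records
with fecal volume percentages (Vf) per ingredient, and per-bear metadata —
assigns phenological seasons, derives reproductive classes, and applies the
dataset-compilation rules with an auditable exclusion log:

* subadults still accompanying their mother are excluded outright;
* spring scats are retained for descriptive tables but flagged
  ``stats_eligible = False`` (spring is unevenly sampled across years and
  reproductive classes, so it stays out of the modelled comparisons).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

from .reference import ReferenceTable, SchemaError, ValidationError

SEXES = frozenset({"F", "M"})
AGE_GROUPS = frozenset({"subadult", "adult"})
REPRODUCTIVE_CLASSES = (
    "lone_female",
    "adult_male",
    "female_with_yearlings",
    "female_with_coy",
    "subadult_female",
    "subadult_male",
)
SEASONS = ("spring", "summer", "fall")

#: Subadults are 1-3 years old; adults 4 years and older.
ADULT_MIN_AGE = 4

#: |sum(Vf) - 100| at or below this renormalizes (when enabled); above rejects.
VF_CLOSURE_TOL = 0.5


@dataclass(frozen=True)
class BearMeta:
    """Demographics of one bear in one sampling context."""

    bear_id: str
    sex: str
    age: int | None = None
    age_group: str | None = None
    reproductive_class: str | None = None
    accompanied_by_mother: bool = False
    with_coy: bool = False
    with_yearlings: bool = False

    def violations(self) -> list[str]:
        v = []
        b = self.bear_id
        if self.sex not in SEXES:
            v.append(f"{b}: sex must be F or M, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            v.append(f"{b}: negative age")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            v.append(f"{b}: unknown age_group {self.age_group!r}")
        if self.age is not None and self.age_group is not None:
            expected = "adult" if self.age >= ADULT_MIN_AGE else "subadult"
            if self.age_group != expected:
                v.append(
                    f"{b}: age {self.age} inconsistent with age_group {self.age_group!r}"
                )
        if (self.with_coy or self.with_yearlings) and self.sex == "M":
            v.append(f"{b}: male flagged with offspring")
        if (
            self.reproductive_class is not None
            and self.reproductive_class not in REPRODUCTIVE_CLASSES
        ):
            v.append(f"{b}: unknown reproductive_class {self.reproductive_class!r}")
        return v


@dataclass(frozen=True)
class ScatRecord:
    """One scat: identifiers, date, mass/volume and the Vf vector."""

    scat_id: str
    bear_id: str
    date: dt.date
    weight_g: float
    volume_ml: float
    vf: dict[str, float]
    season: str | None = None
    stats_eligible: bool = True

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class SeasonCalendar:
    """Phenological season windows for one study area.

    Spring runs from den exit (per-year configurable) to the end of moose
    calving (May 20); summer from May 21 to first berry ripening (July 31);
    fall from August 1 until late October (default October 31).  Dates
    outside these windows are ``out_of_season``.
    """

    spring_start: dict[int, dt.date] = field(default_factory=dict)
    default_spring_start: tuple[int, int] = (4, 15)  # (month, day)
    spring_end: tuple[int, int] = (5, 20)
    summer_start: tuple[int, int] = (5, 21)
    summer_end: tuple[int, int] = (7, 31)
    fall_start: tuple[int, int] = (8, 1)
    fall_end: tuple[int, int] = (10, 31)

    def spring_start_for(self, year: int) -> dt.date:
        if year in self.spring_start:
            return self.spring_start[year]
        m, d = self.default_spring_start
        return dt.date(year, m, d)

    def _d(self, year: int, md: tuple[int, int]) -> dt.date:
        return dt.date(year, md[0], md[1])

    def validate(self, year: int) -> None:
        pts = [
            self.spring_start_for(year),
            self._d(year, self.spring_end),
            self._d(year, self.summer_start),
            self._d(year, self.summer_end),
            self._d(year, self.fall_start),
            self._d(year, self.fall_end),
        ]
        if sorted(pts) != pts:
            raise ValidationError(f"season windows overlap or are out of order in {year}")


def assign_season(date: dt.date, calendar: SeasonCalendar | None = None) -> str:
    """Map a calendar date to spring / summer / fall / out_of_season."""
    cal = calendar or SeasonCalendar()
    y = date.year
    cal.validate(y)
    if cal.spring_start_for(y) <= date <= cal._d(y, cal.spring_end):
        return "spring"
    if cal._d(y, cal.summer_start) <= date <= cal._d(y, cal.summer_end):
        return "summer"
    if cal._d(y, cal.fall_start) <= date <= cal._d(y, cal.fall_end):
        return "fall"
    return "out_of_season"


def derive_reproductive_class(meta: BearMeta) -> str:
    """Derive the six-way reproductive class from sex, age group and cub status.

    Females with dependent offspring take precedence over the lone-female
    class; subadults (1-3 y) are classed by sex regardless of offspring flags
    (which would be invalid for them anyway).
    """
    for msg in meta.violations():
        raise ValidationError(msg)
    if meta.age_group is None and meta.age is None:
        raise ValidationError(f"{meta.bear_id}: need age or age_group")
    group = meta.age_group or ("adult" if meta.age >= ADULT_MIN_AGE else "subadult")
    if group == "subadult":
        return "subadult_female" if meta.sex == "F" else "subadult_male"
    if meta.sex == "M":
        return "adult_male"
    if meta.with_coy:
        return "female_with_coy"
    if meta.with_yearlings:
        return "female_with_yearlings"
    return "lone_female"


def read_bears(path) -> dict[str, BearMeta]:
    """Read the bear metadata CSV into a mapping keyed by ``bear_id``."""
    df = pd.read_csv(path, comment="#", dtype={"bear_id": str})
    required = {"bear_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    bears: dict[str, BearMeta] = {}
    for rec in df.to_dict("records"):
        bid = rec["bear_id"]
        if bid in bears:
            raise ValidationError(f"{path}: duplicate bear_id {bid!r}")
        age = rec.get("age")
        meta = BearMeta(
            bear_id=bid,
            sex=str(rec["sex"]).strip(),
            age=None if pd.isna(age) else int(age),
            age_group=_opt_str(rec.get("age_group")),
            reproductive_class=_opt_str(rec.get("reproductive_class")),
            accompanied_by_mother=_as_bool(rec.get("accompanied_by_mother", False)),
            with_coy=_as_bool(rec.get("with_coy", False)),
            with_yearlings=_as_bool(rec.get("with_yearlings", False)),
        )
        problems = meta.violations()
        if problems:
            raise ValidationError("; ".join(problems))
        if meta.reproductive_class is None:
            try:
                meta = replace(meta, reproductive_class=derive_reproductive_class(meta))
            except ValidationError:
                pass  # insufficient info; left unset, caught at compile time
        bears[bid] = meta
    return bears


def _opt_str(x) -> str | None:
    if x is None or (isinstance(x, float) and pd.isna(x)) or pd.isna(x):
        return None
    s = str(x).strip()
    return s or None


def _as_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    if x is None or pd.isna(x):
        return False
    return str(x).strip().lower() in {"1", "true", "t", "yes", "y"}


def read_scats(
    path,
    reference: ReferenceTable,
    *,
    renormalize: bool = False,
    closure_tol: float = VF_CLOSURE_TOL,
) -> list[ScatRecord]:
    """Read a scat CSV (wide ``vf_<id>`` columns or long triplets).

    Vf vectors must close to 100.  Deviations within ``closure_tol`` are
    renormalized when ``renormalize=True``; anything else rejects the record
    with a message naming it.  Unknown ingredient ids always reject.
    """
    df = pd.read_csv(path, comment="#", dtype={"scat_id": str, "bear_id": str})
    base = {"scat_id", "bear_id", "date", "weight_g", "volume_ml"}
    if {"ingredient_id", "vf_pct"} <= set(df.columns):
        return _scats_from_long(path, df, reference, renormalize, closure_tol)
    missing = base - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    vf_cols = [c for c in df.columns if c.startswith("vf_")]
    if not vf_cols:
        raise SchemaError(f"{path}: no vf_<ingredient_id> columns found")
    unknown = [c[3:] for c in vf_cols if c[3:] not in reference]
    if unknown:
        raise ValidationError(f"{path}: unknown ingredient id(s) {unknown}")
    records = []
    for rec in df.to_dict("records"):
        vf = {c[3:]: float(0 if pd.isna(rec[c]) else rec[c]) for c in vf_cols}
        records.append(_build_scat(rec, vf, renormalize, closure_tol))
    return records


def _scats_from_long(path, df, reference, renormalize, closure_tol):
    meta_cols = {"scat_id", "bear_id", "date", "weight_g", "volume_ml"}
    missing = meta_cols - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: long format missing column(s) {sorted(missing)}")
    unknown = sorted(set(df["ingredient_id"]) - set(reference.ids))
    if unknown:
        raise ValidationError(f"{path}: unknown ingredient id(s) {unknown}")
    records = []
    for sid, grp in df.groupby("scat_id", sort=False):
        head = grp.iloc[0].to_dict()
        vf = dict(zip(grp["ingredient_id"], grp["vf_pct"].astype(float)))
        records.append(_build_scat(head, vf, renormalize, closure_tol))
    return records


def _build_scat(rec, vf, renormalize, closure_tol) -> ScatRecord:
    sid = rec["scat_id"]
    bad = {k: v for k, v in vf.items() if v < 0 or v > 100}
    if bad:
        raise ValidationError(f"scat {sid!r}: Vf outside [0, 100]: {bad}")
    total = sum(vf.values())
    if abs(total - 100.0) > 1e-9:
        if not renormalize or abs(total - 100.0) > closure_tol:
            raise ValidationError(
                f"scat {sid!r}: Vf sums to {total:.3f}, not 100 "
                f"(tolerance {closure_tol}, renormalize={renormalize})"
            )
        vf = {k: v * 100.0 / total for k, v in vf.items()}
    date = rec["date"]
    if not isinstance(date, dt.date):
        date = dt.date.fromisoformat(str(date)[:10])
    return ScatRecord(
        scat_id=str(sid),
        bear_id=str(rec["bear_id"]),
        date=date,
        weight_g=float(0 if pd.isna(rec.get("weight_g")) else rec["weight_g"]),
        volume_ml=float(rec["volume_ml"]),
        vf=vf,
    )


@dataclass(frozen=True)
class Exclusion:
    scat_id: str
    rule: str
    detail: str = ""


def compile_dataset(
    scats: list[ScatRecord],
    bears: dict[str, BearMeta],
    calendar: SeasonCalendar | None = None,
) -> tuple[list[ScatRecord], list[Exclusion]]:
    """Assemble the analysis set, applying the compilation rules.

    Returns ``(analysis_set, exclusion_log)``.  Scats from subadults still
    accompanying their mother are dropped (logged).  Spring and out-of-season
    scats are *retained* with ``stats_eligible=False`` so descriptive tables
    can still show them; flagging is logged but does not remove records, so
    ``len(input) == len(output) + len(exclusions dropped)``.
    """
    cal = calendar or SeasonCalendar()
    missing = sorted({s.bear_id for s in scats} - set(bears))
    if missing:
        raise ValidationError(f"bear_id(s) in scats but not in bear metadata: {missing}")
    out: list[ScatRecord] = []
    log: list[Exclusion] = []
    for s in scats:
        meta = bears[s.bear_id]
        if meta.accompanied_by_mother and (
            meta.age_group == "subadult"
            or (meta.age is not None and meta.age < ADULT_MIN_AGE)
        ):
            log.append(
                Exclusion(s.scat_id, "accompanied_subadult", f"bear {s.bear_id}")
            )
            continue
        season = assign_season(s.date, cal)
        eligible = season in ("summer", "fall")
        out.append(replace(s, season=season, stats_eligible=eligible))
    return out, log


def reproductive_class_of(scat: ScatRecord, bears: dict[str, BearMeta]) -> str:
    meta = bears[scat.bear_id]
    if meta.reproductive_class is not None:
        return meta.reproductive_class
    return derive_reproductive_class(meta)
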