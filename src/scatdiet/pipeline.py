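"""End-to-end orchestration: ingest -> EDC -> nutrients -> summaries -> LMMs.

Everything a run needs sits in one :class:`RunConfig` (loadable from YAML),
so every paper-gap decision — miscellaneous CF convention, Vf closure
tolerance, season pivot dates, Atwater factors, the DM-basis threshold —
is visible and overridable in one place.  A run writes its output tables,
an exclusion log and a manifest with input paths, settings and file
checksums, and is byte-deterministic under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import edc as edc_mod
from . import ingest, stats
from .nutrients import AtwaterFactors, ThresholdSpec, nutrient_table
from .reference import ReferenceTable, builtin_reference, load_reference

log = logging.getLogger("scatdiet")

DEFAULT_SUMMARY_VARIABLES = [
    "edc_cat_fruit",
    "edc_cat_insects",
    "edc_cat_vertebrates",
    "edc_cat_natural_vegetation",
    "edc_cat_anthropogenic_vegetation",
    "cp_dm",
    "ee_dm",
    "nfe_dm",
    "tdf_dm",
    "ash_dm",
    "cp_me",
    "ee_me",
    "nfe_me",
    "protein_ratio_dm",
    "protein_ratio_me",
    "nonfat_fat_dm",
    "nonfat_fat_me",
]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; ``from_yaml`` reads the same fields."""

    reference_path: str | None = None  # None -> packaged illustrative table
    scats_path: str = "scats.csv"
    bears_path: str = "bears.csv"
    out_dir: str = "out"
    renormalize_vf: bool = False
    vf_closure_tol: float = ingest.VF_CLOSURE_TOL
    misc_threshold_pct: float = edc_mod.MISC_THRESHOLD_PCT
    misc_cf: float | None = None  # None -> per-scat mean of identified CFs
    dm_threshold: float = 3.55
    kj_per_g_protein: float = 16.72
    kj_per_g_fat: float = 37.62
    kj_per_g_nfe: float = 16.72
    spring_start: dict = field(default_factory=dict)  # year -> ISO date
    fall_end: tuple[int, int] = (10, 31)
    alpha: float = 0.05
    df_method: str = "residual"
    responses: list[str] = field(default_factory=lambda: ["cp_dm", "nonfat_fat_dm"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "fall_end" in raw:
            raw["fall_end"] = tuple(raw["fall_end"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["fall_end"] = list(self.fall_end)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def atwater(self) -> AtwaterFactors:
        return AtwaterFactors(
            kj_per_g_protein=self.kj_per_g_protein,
            kj_per_g_fat=self.kj_per_g_fat,
            kj_per_g_nfe=self.kj_per_g_nfe,
        )

    def threshold(self) -> ThresholdSpec:
        return ThresholdSpec(dm_min=self.dm_threshold, atwater=self.atwater())

    def calendar(self) -> ingest.SeasonCalendar:
        import datetime as dt

        starts = {
            int(y): dt.date.fromisoformat(str(d)) for y, d in self.spring_start.items()
        }
        return ingest.SeasonCalendar(spring_start=starts, fall_end=self.fall_end)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the artifact manifest."""
    for p in (config.scats_path, config.bears_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    reference = (
        load_reference(config.reference_path)
        if config.reference_path
        else builtin_reference()
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scats = ingest.read_scats(
        config.scats_path,
        reference,
        renormalize=config.renormalize_vf,
        closure_tol=config.vf_closure_tol,
    )
    bears = ingest.read_bears(config.bears_path)
    compiled, exclusions = ingest.compile_dataset(scats, bears, config.calendar())
    log.info("ingest: %d scats in, %d compiled, %d excluded",
             len(scats), len(compiled), len(exclusions))

    frame = build_analysis_frame(
        compiled,
        bears,
        reference,
        misc_threshold_pct=config.misc_threshold_pct,
        misc_cf=config.misc_cf,
        atwater=config.atwater(),
        threshold=config.threshold(),
    )
    log.info("edc/nutrients: %d scats kept after miscellaneous filter",
             int((~frame["misc_dropped"]).sum()))

    files: dict[str, Path] = {}
    excl_df = pd.DataFrame(
        [dataclasses.asdict(e) for e in exclusions],
        columns=["scat_id", "rule", "detail"],
    )
    files["exclusions"] = out / "exclusions.csv"
    excl_df.to_csv(files["exclusions"], index=False)

    files["edc"] = out / "edc.csv"
    edc_cols = ["scat_id"] + [c for c in frame.columns if c.startswith("edc_")] + [
        "misc_dropped"
    ]
    frame[edc_cols].to_csv(files["edc"], index=False)

    files["nutrients"] = out / "nutrients.csv"
    nut_cols = ["scat_id"] + [
        c
        for c in frame.columns
        if c in stats_columns()
    ]
    frame.loc[~frame["misc_dropped"], nut_cols].to_csv(files["nutrients"], index=False)

    analysis = frame[~frame["misc_dropped"]]
    variables = [v for v in DEFAULT_SUMMARY_VARIABLES if v in analysis.columns]
    for keys in (["season"], ["year", "season"], ["season", "reproductive_class"]):
        tab = stats.stratified_summary(analysis, keys, variables)
        name = "summary_" + "_".join(keys)
        files[name] = out / f"{name}.csv"
        tab.to_csv(files[name], index=False)

    for response in config.responses:
        spec = stats.ModelSpec(response=response, alpha=config.alpha)
        try:
            fit = stats.fit_lmm_backward(spec, analysis)
        except stats.ModelError as exc:
            log.warning("lmm %s skipped: %s", response, exc)
            continue
        name = f"lmm_{response}"
        files[name] = out / f"{name}.txt"
        _write_lmm_report(fit, files[name])
        for factor in fit.retained_main:
            contrasts = stats.posthoc_pairwise(fit, factor, df_method=config.df_method)
            cname = f"contrasts_{response}_{factor}"
            files[cname] = out / f"{cname}.csv"
            contrasts.to_csv(files[cname], index=False)
        diag = stats.residual_diagnostics(fit, seed=config.seed)
        dname = f"diagnostics_{response}"
        files[dname] = out / f"{dname}.csv"
        diag["table"].assign(shapiro_w=diag["shapiro_w"]).to_csv(
            files[dname], index=False
        )

    manifest = {
        "inputs": {
            "scats": str(config.scats_path),
            "bears": str(config.bears_path),
            "reference": config.reference_path or "builtin",
        },
        "settings": {
            "misc_threshold_pct": config.misc_threshold_pct,
            "misc_cf": config.misc_cf if config.misc_cf is not None else "scat-mean",
            "dm_threshold": config.dm_threshold,
            "me_threshold": config.threshold().me_min,
            "alpha": config.alpha,
            "df_method": config.df_method,
            "seed": config.seed,
        },
        "counts": {
            "scats_in": len(scats),
            "compiled": len(compiled),
            "excluded": len(exclusions),
            "misc_dropped": int(frame["misc_dropped"].sum()),
            "stats_eligible": int(analysis["stats_eligible"].sum()),
        },
        "files": {k: {"path": str(v), "sha256": _checksum(v)} for k, v in files.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def stats_columns() -> list[str]:
    return [
        "cp_dm", "ee_dm", "nfe_dm", "tdf_dm", "ash_dm",
        "cp_me", "ee_me", "nfe_me", "me_density_kj_g",
        "protein_ratio_dm", "protein_ratio_me",
        "nonfat_fat_dm", "nonfat_fat_me",
        "below_thr_dm", "below_thr_me",
    ]


def build_analysis_frame(
    compiled: list,
    bears: dict,
    reference: ReferenceTable,
    *,
    misc_threshold_pct: float = edc_mod.MISC_THRESHOLD_PCT,
    misc_cf: float | None = None,
    atwater: AtwaterFactors | None = None,
    threshold: ThresholdSpec | None = None,
) -> pd.DataFrame:
    """One row per compiled scat: labels + EDC + nutrients + ratios + flags.

    Scats dropped by the miscellaneous rule keep their EDC columns but have
    ``misc_dropped=True`` and no nutrient values.
    """
    edc_df = edc_mod.edc_table(
        compiled, reference, threshold_pct=misc_threshold_pct, misc_cf=misc_cf
    )
    kept_vectors = {}
    for s in compiled:
        vec = edc_mod.compute_edc(s.vf, reference, misc_cf=misc_cf)
        keep, _ = edc_mod.misc_filter(vec, reference, misc_threshold_pct)
        if keep:
            kept_vectors[s.scat_id] = edc_mod.drop_misc_and_reclose(vec, reference)
    nut_df = nutrient_table(
        compiled, kept_vectors, reference, atwater=atwater, threshold=threshold
    )
    labels = pd.DataFrame(
        {
            "scat_id": [s.scat_id for s in compiled],
            "bear_id": [s.bear_id for s in compiled],
            "date": [s.date for s in compiled],
            "year": [s.year for s in compiled],
            "season": [s.season for s in compiled],
            "stats_eligible": [s.stats_eligible for s in compiled],
            "reproductive_class": [
                ingest.reproductive_class_of(s, bears) for s in compiled
            ],
        }
    )
    frame = labels.merge(edc_df, on="scat_id", how="left")
    return frame.merge(nut_df, on="scat_id", how="left")


def _write_lmm_report(fit: stats.FittedLMM, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"response: {fit.spec.response}\n")
        fh.write(f"retained terms: {', '.join(fit.retained_terms) or '(intercept only)'}\n")
        fh.write("selection log:\n")
        for entry in fit.elimination_log:
            fh.write(
                f"  step {entry['step']}: {entry['action']} {entry['term']} "
                f"(p={entry['p']:.4f})\n"
            )
        fh.write("\n")
        fh.write(str(fit.result.summary()))
        fh.write("\n")
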