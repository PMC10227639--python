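"""Estimated dietary content (EDC): digestibility-corrected diet composition.

Fecal volume proportions under-represent highly digestible foods.  The EDC
transform reweights each ingredient's fecal volume share ``Vf_i`` by its
correction factor ``CF_i`` (g DM ingested per mL residue) and re-closes to
100:

    EDC_i = 100 * Vf_i * CF_i / sum_j Vf_j * CF_j

so EDC_i is the percent of ingested dry matter attributed to ingredient i.
Unidentifiable matter ("miscellaneous") has no defensible correction factor;
by default it borrows the mean CF of the identified ingredients present in
the same scat (configurable to a fixed constant).  Scats whose miscellaneous
EDC exceeds 5% are dropped to prevent an unattributable fraction from
leveraging the nutrient profile; in scats that are kept, the residual misc
share is removed and the EDC re-closed over identified ingredients before
any nutrient computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import CATEGORIES, ReferenceTable

#: Scats with miscellaneous EDC strictly above this % are omitted.
MISC_THRESHOLD_PCT = 5.0

CLOSURE_ATOL = 1e-9


class DegenerateInputError(ValueError):
    """All-zero or otherwise information-free input vector."""


@dataclass(frozen=True)
class EdcVector:
    """Per-ingredient % of ingested dry matter, closed to 100."""

    values: dict[str, float]

    def __getitem__(self, ingredient_id: str) -> float:
        return self.values.get(ingredient_id, 0.0)

    def total(self) -> float:
        return sum(self.values.values())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def compute_edc(
    vf: dict[str, float],
    reference: ReferenceTable,
    *,
    misc_cf: float | None = None,
) -> EdcVector:
    """Apply the correction-factor transform to a Vf vector.

    ``misc_cf`` overrides the default miscellaneous correction factor (mean
    CF of identified ingredients present in the scat).  Ingredients with
    zero Vf are carried through as explicit zeros so vectors stay alignable.
    """
    if not vf or all(v == 0 for v in vf.values()):
        raise DegenerateInputError("Vf vector is empty or all zero")
    misc_id = reference.misc_id
    present_identified = [
        k for k, v in vf.items() if v > 0 and k != misc_id
    ]
    missing = [k for k in present_identified if reference[k].cf is None]
    if missing:
        raise ValueError(f"no correction factor for ingredient(s) {missing}")
    if misc_id in vf and vf.get(misc_id, 0) > 0:
        if misc_cf is None:
            if not present_identified:
                raise DegenerateInputError(
                    "scat is pure miscellaneous; no identified CF to borrow"
                )
            misc_cf = float(
                np.mean([reference[k].cf for k in present_identified])
            )
        elif misc_cf <= 0:
            raise ValueError("misc_cf must be positive")

    def cf_of(k: str) -> float:
        return misc_cf if k == misc_id else reference[k].cf

    weights = {k: v * cf_of(k) if v > 0 else 0.0 for k, v in vf.items()}
    denom = sum(weights.values())
    return EdcVector({k: 100.0 * w / denom for k, w in weights.items()})


def misc_filter(
    edc: EdcVector,
    reference: ReferenceTable,
    threshold_pct: float = MISC_THRESHOLD_PCT,
) -> tuple[bool, str]:
    """Decide whether a scat is kept under the miscellaneous-EDC rule.

    Returns ``(keep, reason)``.  The rule is strict: a scat is dropped only
    when misc EDC *exceeds* the threshold, so exactly 5% is kept.
    """
    misc_id = reference.misc_id
    share = edc[misc_id] if misc_id else 0.0
    if share > threshold_pct:
        return False, f"miscellaneous EDC {share:.2f}% > {threshold_pct:g}%"
    return True, f"miscellaneous EDC {share:.2f}% <= {threshold_pct:g}%"


def drop_misc_and_reclose(edc: EdcVector, reference: ReferenceTable) -> EdcVector:
    """Remove the miscellaneous share and re-close to 100 over identified items.

    Nutrient composition cannot be attributed to unidentifiable matter, so
    after the misc filter keeps a scat the residual misc share is discarded
    and the remaining EDC rescaled.  No-op when misc is absent.
    """
    misc_id = reference.misc_id
    kept = {k: v for k, v in edc.values.items() if k != misc_id}
    total = sum(kept.values())
    if total <= 0:
        raise DegenerateInputError("no identified EDC remains after removing misc")
    return EdcVector({k: 100.0 * v / total for k, v in kept.items()})


def group_categories(edc: EdcVector, reference: ReferenceTable) -> dict[str, float]:
    """Roll ingredient EDC up to the six primary categories (sums preserved)."""
    out = {c: 0.0 for c in CATEGORIES}
    for k, v in edc.values.items():
        out[reference.category_of(k)] += v
    return out


def edc_table(
    scats,
    reference: ReferenceTable,
    *,
    threshold_pct: float = MISC_THRESHOLD_PCT,
    misc_cf: float | None = None,
) -> pd.DataFrame:
    """Per-scat EDC output table.

    One row per scat with per-ingredient ``edc_<id>`` columns (computed
    before misc removal), per-category ``edc_cat_<category>`` rollups, and a
    ``misc_dropped`` flag from the miscellaneous rule.  Rows flagged
    ``misc_dropped`` should be excluded from nutrient computation.
    """
    rows = []
    for s in scats:
        edc = compute_edc(s.vf, reference, misc_cf=misc_cf)
        keep, reason = misc_filter(edc, reference, threshold_pct)
        cats = group_categories(edc, reference)
        row = {"scat_id": s.scat_id}
        row.update({f"edc_{k}": v for k, v in edc.values.items()})
        row.update({f"edc_cat_{c}": v for c, v in cats.items()})
        row["misc_dropped"] = not keep
        row["misc_rule"] = reason
        rows.append(row)
    return pd.DataFrame(rows)
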