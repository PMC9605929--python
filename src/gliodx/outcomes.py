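"""Deterministic lesion- and patient-level outcome adjudication.

Rules follow the modified RANO response criteria adapted to a 6-month
(± 2 weeks) evaluation window, with precedence

    histology  >  MRI (bidimensional products / new lesions)  >  clinical,

where MRI progression is a >= 25% increase in the product of perpendicular
lesion diameters at a follow-up at least 4 weeks later, any new enhancing
lesion, or explicitly flagged progression of non-enhancing disease;
regression is a > 50% product reduction.  Histology adjudicates even outside
the window (late confirmatory surgery counts).  "Significant progression of
non-enhancing lesions" and "clear clinical deterioration" are boolean inputs
— no quantitative rule exists for them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

PROGRESSIVE = "progressive"
NON_PROGRESSIVE = "non-progressive"
NON_EVALUABLE = "non-evaluable"

#: evaluation window: 6 months ± 2 weeks
WINDOW_DAYS = (182, 14)
MIN_FOLLOWUP_MRI_DAYS = 28


@dataclasses.dataclass(frozen=True)
class FollowUpRecord:
    """Follow-up evidence for one lesion.

    ``products_mm2`` are serial bidimensional diameter products with their
    day offsets from the index scan; the first entry is the index-scan
    baseline.  ``histology`` is 'tumour', 'no-tumour' or 'none'.
    """

    lesion_id: str
    histology: str = "none"
    histology_day: float | None = None
    product_days: tuple = ()
    products_mm2: tuple = ()
    new_enhancing_lesion: bool = False
    nonenhancing_progression: bool = False
    clinical_progression: bool = False

    def __post_init__(self) -> None:
        if self.histology not in ("tumour", "no-tumour", "none"):
            raise ValueError("histology must be 'tumour', 'no-tumour' or 'none'")
        if len(self.product_days) != len(self.products_mm2):
            raise ValueError("product series and dates differ in length")
        days = list(self.product_days)
        if days != sorted(days):
            raise ValueError("product dates must be increasing")
        if any(p < 0 for p in self.products_mm2):
            raise ValueError("diameter products must be >= 0")


def adjudicate_outcome(
    record: FollowUpRecord, window_days: tuple[int, int] = WINDOW_DAYS
) -> tuple[str, str]:
    """Adjudicate one lesion; returns (label, reason).

    Exactly one of 'progressive' / 'non-progressive' / 'non-evaluable' is
    returned; the function is pure in the record.
    """
    hi = window_days[0] + window_days[1]

    # precedence 1: histopathology (any day — late confirmatory surgery counts)
    if record.histology == "tumour":
        return PROGRESSIVE, "histology: tumour"
    if record.histology == "no-tumour":
        if record.clinical_progression:
            return NON_EVALUABLE, "conflicting; clinical decision required"
        return NON_PROGRESSIVE, "histology: no tumour"

    # precedence 2: MRI follow-up within the window, at least 4 weeks later
    if record.new_enhancing_lesion:
        return PROGRESSIVE, "MRI: new enhancing lesion"
    if record.nonenhancing_progression:
        return PROGRESSIVE, "MRI: progression of non-enhancing lesion"
    baseline = record.products_mm2[0] if record.products_mm2 else None
    followups = [
        p
        for d, p in zip(record.product_days, record.products_mm2)
        if MIN_FOLLOWUP_MRI_DAYS <= d <= hi
    ]
    if baseline is not None and baseline > 0 and followups:
        if any(p >= 1.25 * baseline for p in followups):
            return PROGRESSIVE, "MRI: >=25% increase in diameter product"
        if followups[-1] < 0.5 * baseline:
            return NON_PROGRESSIVE, "MRI: >50% reduction (regression)"
        return NON_PROGRESSIVE, "MRI: stable"

    # precedence 3: clinical adjudication
    if record.clinical_progression:
        return PROGRESSIVE, "clinical: deterioration attributed to tumour"
    return NON_EVALUABLE, "no qualifying evidence within window"


def patient_outcome(lesion_labels: Sequence[str]) -> str:
    """Patient label: progressive if any lesion is, non-progressive if all
    evaluable lesions are non-progressive, else non-evaluable."""
    labels = list(lesion_labels)
    if PROGRESSIVE in labels:
        return PROGRESSIVE
    if any(l == NON_PROGRESSIVE for l in labels):
        if all(l in (NON_PROGRESSIVE, NON_EVALUABLE) for l in labels):
            return NON_PROGRESSIVE
    return NON_EVALUABLE if labels else NON_EVALUABLE


def adjudicate_table(followup: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate a follow-up CSV (one row per lesion).

    Expected columns: lesion_id, histology, histology_day, baseline_mm2,
    followup_day, followup_mm2, new_enhancing_lesion,
    nonenhancing_progression, clinical_progression.  Missing columns default
    to no evidence.  Returns lesion_id, outcome, reason.
    """
    def get(row, col, default):
        v = row.get(col, default)
        return default if pd.isna(v) else v

    out = []
    for _, row in followup.iterrows():
        days, prods = (), ()
        if not pd.isna(row.get("baseline_mm2", float("nan"))):
            days, prods = (0.0,), (float(row["baseline_mm2"]),)
            if not pd.isna(row.get("followup_mm2", float("nan"))):
                days += (float(get(row, "followup_day", 182.0)),)
                prods += (float(row["followup_mm2"]),)
        rec = FollowUpRecord(
            lesion_id=str(row["lesion_id"]),
            histology=str(get(row, "histology", "none")),
            histology_day=get(row, "histology_day", None),
            product_days=days,
            products_mm2=prods,
            new_enhancing_lesion=bool(get(row, "new_enhancing_lesion", False)),
            nonenhancing_progression=bool(get(row, "nonenhancing_progression", False)),
            clinical_progression=bool(get(row, "clinical_progression", False)),
        )
        label, reason = adjudicate_outcome(rec)
        out.append({"lesion_id": rec.lesion_id, "outcome": label, "reason": reason})
    return pd.DataFrame(out)
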