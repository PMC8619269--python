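"""Composite discriminant score separating alpha- from beta-thalassaemia trait.

The score combines the three analyzer quantities that best separate the
two carrier states — the reticulocyte lower-median-angle light scatter
channel (elevated in beta-trait), the red-cell distribution width
(elevated in beta-trait) and the mean corpuscular haemoglobin (lowered in
beta-trait)::

    score = MN-LMALS-RET x RDW - MCH

Scores above the decision cutoff (default 1742.5) call beta-thalassaemia
trait; scores at or below it call alpha-thalassaemia trait. A tie at
exactly the cutoff goes to the alpha (negative) class, because the beta
call is defined strictly by "score > cutoff".

A microcytosis pre-screen (MCH < 27 pg, MCV < 80 fL, RDW > 14 %) flags
subjects who warrant carrier work-up at all; by default it is reported
alongside the score rather than gating it. Classical red-cell
discriminant indices from the thalassaemia-screening literature (Mentzer,
Shine & Lal, England & Fraser, Ehsani, Srivastava, Green & King, RDW
index) are computed for comparison output only — their published cutoffs
are never applied to make calls here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .datamodel_io import Cohort, SubjectRecord

__all__ = [
    "ALPHA_CALL",
    "BETA_CALL",
    "NOT_EVALUABLE",
    "AB_SCORE_FIELDS",
    "ScreeningConfig",
    "ScoreResult",
    "ab_score",
    "classify",
    "prescreen",
    "classical_indices",
    "score_cohort",
]

ALPHA_CALL = "alpha_trait"
BETA_CALL = "beta_trait"
NOT_EVALUABLE = "not_evaluable"

#: The only fields the composite score needs.
AB_SCORE_FIELDS = ("mn_lmals_ret", "rdw", "mch")

PRESCREEN_FIELDS = ("mch", "mcv", "rdw")


@dataclass(frozen=True)
class ScreeningConfig:
    """Decision thresholds for scoring and pre-screening.

    cutoff: score decision threshold (beta strictly above).
    mch_max (pg), mcv_max (fL), rdw_min (%): microcytosis pre-screen
    thresholds; ``screen_combination`` chooses whether any criterion
    suffices ("any", the conservative screening reading — fewer missed
    carriers) or all must fire ("all").
    """

    cutoff: float = 1742.5
    mch_max: float = 27.0
    mcv_max: float = 80.0
    rdw_min: float = 14.0
    screen_combination: str = "any"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        for name in ("mch_max", "mcv_max", "rdw_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.screen_combination not in {"any", "all"}:
            raise ValueError("screen_combination must be 'any' or 'all'")


@dataclass(frozen=True)
class ScoreResult:
    subject_id: str
    score: float  # NaN when not evaluable
    call: str  # alpha_trait | beta_trait | not_evaluable
    screened_in: Optional[bool]  # None when pre-screen inputs missing


def ab_score(record: SubjectRecord, strict: bool = True) -> float:
    """Composite score ``mn_lmals_ret * rdw - mch`` at full float precision.

    In strict mode a missing or flagged required field raises
    ``ValueError``; otherwise NaN is returned (batch semantics).
    """
    if not record.has(*AB_SCORE_FIELDS):
        if strict:
            missing = [f for f in AB_SCORE_FIELDS if not record.has(f)]
            raise ValueError(
                f"{record.subject_id}: score not evaluable, "
                f"missing/flagged fields {missing}"
            )
        return math.nan
    return record.mn_lmals_ret * record.rdw - record.mch


def classify(score: float, config: ScreeningConfig = ScreeningConfig()) -> str:
    """Beta-trait if score > cutoff, else alpha-trait (ties go alpha)."""
    if not math.isfinite(score):
        raise ValueError(f"cannot classify non-finite score {score!r}")
    return BETA_CALL if score > config.cutoff else ALPHA_CALL


def prescreen(
    record: SubjectRecord, config: ScreeningConfig = ScreeningConfig()
) -> Optional[bool]:
    """Microcytosis pre-screen; None when mch/mcv/rdw are unavailable."""
    if not record.has(*PRESCREEN_FIELDS):
        return None
    hits = (
        record.mch < config.mch_max,
        record.mcv < config.mcv_max,
        record.rdw > config.rdw_min,
    )
    return all(hits) if config.screen_combination == "all" else any(hits)


#: index name -> (formula, required fields); values per the screening
#: literature each index originates from.
_CLASSICAL = {
    "mentzer": (lambda r: r.mcv / r.rbc, ("mcv", "rbc")),
    "shine_lal": (lambda r: r.mcv**2 * r.mch / 100.0, ("mcv", "mch")),
    "england_fraser": (
        lambda r: r.mcv - r.rbc - 5.0 * r.hb - 3.4,
        ("mcv", "rbc", "hb"),
    ),
    "ehsani": (lambda r: r.mcv - 10.0 * r.rbc, ("mcv", "rbc")),
    "srivastava": (lambda r: r.mch / r.rbc, ("mch", "rbc")),
    "green_king": (
        lambda r: r.mcv**2 * r.rdw / (100.0 * r.hb),
        ("mcv", "rdw", "hb"),
    ),
    "rdw_index": (lambda r: r.mcv * r.rdw / r.rbc, ("mcv", "rdw", "rbc")),
}


def classical_indices(record: SubjectRecord) -> dict[str, float]:
    """Literature discriminant indices for microcytic anaemia work-up.

    Returns a name->value mapping; an index whose inputs are missing or
    whose denominator is zero maps to NaN (the others are still
    returned). Formulas: Mentzer MCV/RBC; Shine&Lal MCV^2*MCH/100;
    England&Fraser MCV-RBC-5*Hb-3.4; Ehsani MCV-10*RBC; Srivastava
    MCH/RBC; Green&King MCV^2*RDW/(100*Hb); RDW index MCV*RDW/RBC.
    """
    out: dict[str, float] = {}
    for name, (formula, fields) in _CLASSICAL.items():
        if not record.has(*fields):
            out[name] = math.nan
            continue
        try:
            out[name] = formula(record)
        except ZeroDivisionError:
            out[name] = math.nan
    return out


def score_cohort(
    cohort: Cohort,
    config: ScreeningConfig = ScreeningConfig(),
    include_classical: bool = False,
) -> pd.DataFrame:
    """Score every subject; one row per subject, nobody silently dropped.

    Subjects whose required inputs are missing or flagged get
    ``call = not_evaluable`` and a NaN score. Columns: subject_id,
    screened_in, score, call (+ the classical indices on request).
    """
    rows = []
    for rec in cohort:
        s = ab_score(rec, strict=False)
        call = classify(s, config) if math.isfinite(s) else NOT_EVALUABLE
        row = {
            "subject_id": rec.subject_id,
            "screened_in": prescreen(rec, config),
            "score": s,
            "call": call,
        }
        if rec.label is not None:
            row["label"] = rec.label
        if include_classical:
            row.update(classical_indices(rec))
        rows.append(row)
    return pd.DataFrame(rows)
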