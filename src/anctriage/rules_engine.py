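"""Traffic-light classification of home-visit measurements.

Three priority conditions are triaged per visit — raised blood pressure
(including an elevated shock index), anaemia, and glucose intolerance on a
2-hour non-fasting OGTT — each to an ordered GREEN < YELLOW < RED colour.
Red means urgent referral, yellow referral, green normal. Band edges live in
a versioned config file (see :mod:`anctriage._config`); every band is
lower-inclusive, so a value exactly at an edge takes the more severe colour.

The classifiers here are written table-style (worst severity across
per-measurement bands). The structurally independent re-implementation used
for concordance checking lives in :mod:`anctriage.validation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import IntEnum
from typing import Optional, Tuple

from ._config import Thresholds, load_recommendations, load_thresholds
from .derived import DomainError, compute_derived, shock_index
from .records import ParticipantRecord, VisitRecord, VisitType

__all__ = [
    "TrafficLight",
    "Recommendation",
    "Assessment",
    "classify_bp",
    "classify_hb",
    "classify_ogtt",
    "case_colors_and_codes",
    "assess_visit",
    "enrolment_eligible",
    "visit_window",
    "ELIGIBLE_GA_MIN_DAYS",
    "ELIGIBLE_GA_MAX_DAYS",
]


class TrafficLight(IntEnum):
    """Severity-ordered triage colour."""

    GREEN = 0
    YELLOW = 1
    RED = 2


@dataclass(frozen=True)
class Recommendation:
    code: str
    text: str


@dataclass(frozen=True)
class Assessment:
    """Per-condition colours, overall severity, and ordered recommendations
    for one visit."""

    participant_id: str
    visit_type: Optional[VisitType]
    bp_color: TrafficLight
    hb_color: TrafficLight
    gdm_color: Optional[TrafficLight]  # None when not screened at this visit
    overall_color: TrafficLight
    recommendations: Tuple[Recommendation, ...]
    missing_practices: Tuple[str, ...]
    derived: object = None


# gestational-age eligibility: 28+0 through 36+6 completed weeks
ELIGIBLE_GA_MIN_DAYS = 196
ELIGIBLE_GA_MAX_DAYS = 258


def _band(value: float, yellow_at: float, red_at: float) -> TrafficLight:
    """Lower-inclusive upward bands: value >= red_at is RED, >= yellow_at
    YELLOW, else GREEN."""
    if value >= red_at:
        return TrafficLight.RED
    if value >= yellow_at:
        return TrafficLight.YELLOW
    return TrafficLight.GREEN


def classify_bp(sbp: float, dbp: float, heart_rate: float,
                thresholds: Thresholds | None = None) -> TrafficLight:
    """Blood-pressure triage: worst of the hypertension bands (systolic,
    diastolic) and the shock-index band."""
    if sbp is None or dbp is None or heart_rate is None:
        raise DomainError("sbp, dbp and heart_rate are all required")
    t = thresholds or load_thresholds()
    si = shock_index(heart_rate, sbp)
    return max(
        _band(sbp, t.sbp_yellow, t.sbp_red),
        _band(dbp, t.dbp_yellow, t.dbp_red),
        _band(si, t.si_yellow, t.si_red),
    )


def classify_hb(hb: float, thresholds: Thresholds | None = None) -> TrafficLight:
    """Anaemia triage: severe below the red edge, mild/moderate below the
    yellow edge, normal otherwise."""
    if hb is None:
        raise DomainError("hb is required")
    t = thresholds or load_thresholds()
    if hb < t.hb_red_below:
        return TrafficLight.RED
    if hb < t.hb_yellow_below:
        return TrafficLight.YELLOW
    return TrafficLight.GREEN


def classify_ogtt(glucose_2h: float, thresholds: Thresholds | None = None) -> TrafficLight:
    """2-hour non-fasting OGTT triage. A missing value is a distinct
    "not screened" outcome handled by the caller, not a colour."""
    if glucose_2h is None:
        raise DomainError("glucose value required; absence means not screened")
    t = thresholds or load_thresholds()
    return _band(glucose_2h, t.ogtt_yellow_at, t.ogtt_red_at)


# recommendation codes per (condition, severity); BP, Hb, GDM condition order
def _clinical_codes(bp_color: TrafficLight, hb_color: TrafficLight,
                    gdm_color: Optional[TrafficLight], hb: float,
                    t: Thresholds) -> list[str]:
    """Ordered clinical recommendation codes: RED items first, then YELLOW,
    stable by condition order (BP, Hb, GDM) within severity."""
    reds: list[str] = []
    yellows: list[str] = []
    if bp_color is TrafficLight.RED:
        reds.append("HTN_SEVERE_URGENT")
    elif bp_color is TrafficLight.YELLOW:
        yellows.append("HTN_REFER")
    if hb_color is TrafficLight.RED:
        reds.append("ANEMIA_SEVERE_URGENT")
    elif hb_color is TrafficLight.YELLOW:
        yellows.append("ANEMIA_MOD_REFER" if hb < t.hb_referral_below else "ANEMIA_MILD_COUNSEL")
    if gdm_color is TrafficLight.RED:
        reds.append("DM_OVERT_URGENT")
    elif gdm_color is TrafficLight.YELLOW:
        yellows.append("GDM_REFER")
    return reds + yellows


def case_colors_and_codes(sbp: float, dbp: float, heart_rate: float, hb: float,
                          glucose_2h: Optional[float],
                          thresholds: Thresholds | None = None):
    """Classify one measurement set; returns (bp, hb, gdm, overall, codes).

    ``gdm`` is None when no OGTT value is supplied ("not screened").
    This is the engine side of the concordance check.
    """
    t = thresholds or load_thresholds()
    bp_color = classify_bp(sbp, dbp, heart_rate, t)
    hb_color = classify_hb(hb, t)
    gdm_color = None if glucose_2h is None else classify_ogtt(glucose_2h, t)
    present = [c for c in (bp_color, hb_color, gdm_color) if c is not None]
    overall = max(present)
    codes = tuple(_clinical_codes(bp_color, hb_color, gdm_color, hb, t))
    return bp_color, hb_color, gdm_color, overall, codes


def _missing_practices(visit: VisitRecord) -> list[str]:
    flags = []
    if not visit.gdm_screened:
        flags.append("gdm_not_screened")
    if visit.ogtt_2h_glucose is None:
        if visit.visit_type is VisitType.postpartum_week6:
            flags.append("repeat_ogtt_missing")
        elif not visit.ogtt_done:
            flags.append("ogtt_missing")
    if not visit.ifa_supplied:
        flags.append("ifa_not_supplied")
    return flags


_PROMPT_FOR_FLAG = {
    "gdm_not_screened": "PROMPT_GDM_SCREEN",
    "ogtt_missing": "PROMPT_OGTT",
    "repeat_ogtt_missing": "PROMPT_REPEAT_OGTT",
    "ifa_not_supplied": "PROMPT_IFA",
}


def assess_visit(participant: ParticipantRecord, visit: VisitRecord,
                 thresholds: Thresholds | None = None,
                 catalogue: dict[str, str] | None = None) -> Assessment:
    """Full per-visit assessment: per-condition colours, overall severity
    (the maximum over conditions present), ordered recommendations, and
    missing ANC-practice flags."""
    if visit.participant_id != participant.participant_id:
        raise DomainError("visit does not belong to participant")
    t = thresholds or load_thresholds()
    cat = catalogue or load_recommendations()
    try:
        bp_color, hb_color, gdm_color, overall, codes = case_colors_and_codes(
            visit.sbp, visit.dbp, visit.heart_rate, visit.hb,
            visit.ogtt_2h_glucose, t)
    except DomainError as exc:
        raise DomainError(f"visit {visit.participant_id}/{visit.visit_type.value}: {exc}") from exc
    missing = _missing_practices(visit)
    all_codes = list(codes) + [_PROMPT_FOR_FLAG[f] for f in missing]
    recs = tuple(Recommendation(code=c, text=cat.get(c, "")) for c in all_codes)
    return Assessment(
        participant_id=participant.participant_id,
        visit_type=visit.visit_type,
        bp_color=bp_color,
        hb_color=hb_color,
        gdm_color=gdm_color,
        overall_color=overall,
        recommendations=recs,
        missing_practices=tuple(missing),
        derived=compute_derived(participant, visit),
    )


def enrolment_eligible(ga_days: int) -> bool:
    """True iff gestational age is within 28+0 .. 36+6 completed weeks."""
    if ga_days < 0:
        raise DomainError("gestational age must be non-negative")
    return ELIGIBLE_GA_MIN_DAYS <= ga_days <= ELIGIBLE_GA_MAX_DAYS


def visit_window(visit_type: VisitType, lmp_date: date,
                 delivery_date: Optional[date] = None) -> tuple[date, date]:
    """Inclusive [start, end] scheduling window for each protocol visit."""
    if visit_type is VisitType.antenatal:
        return (lmp_date + timedelta(days=ELIGIBLE_GA_MIN_DAYS),
                lmp_date + timedelta(days=ELIGIBLE_GA_MAX_DAYS))
    if delivery_date is None:
        raise DomainError("delivery_date required for postpartum windows")
    if visit_type is VisitType.postpartum_week1:
        return (delivery_date, delivery_date + timedelta(days=7))
    if visit_type is VisitType.postpartum_week6:
        return (delivery_date + timedelta(days=36), delivery_date + timedelta(days=48))
    raise DomainError(f"unknown visit type {visit_type!r}")
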