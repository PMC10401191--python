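"""Feasibility, acceptability and clinical summary statistics for a
(real-schema or simulated) two-arm cohort: retention, condition prevalence,
visit fidelity, screening coverage, arm-comparison table and recruitment
rates.

Display rounding follows trial-report conventions: whole percents
(half-up) for proportions, one decimal for means/SDs, p to two decimals
with a ">.99" convention; prevalence keeps one decimal where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .derived import age_years, bmi
from .records import Arm, ParticipantRecord, VisitRecord, VisitType
from .rules_engine import TrafficLight, classify_bp, classify_ogtt, visit_window

__all__ = [
    "Condition",
    "RetentionSummary",
    "PrevalenceResult",
    "ScreeningSummary",
    "ComparisonRow",
    "RecruitmentCluster",
    "TrialSummary",
    "retention_summary",
    "prevalence",
    "fidelity_summary",
    "screening_summary",
    "comparison_table",
    "recruitment_summary",
    "expected_schedule",
    "summarize",
    "round_half_up",
    "format_p",
]

DAYS_PER_MONTH = 30.44
ANEMIA_HB_THRESHOLD = 10.0  # g/dL: moderate-to-severe anaemia definition


class Condition(str, Enum):
    anemia_lt10 = "anemia_lt10"
    hdp = "hdp"
    gdm = "gdm"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (display convention; avoids banker's
    rounding turning 81.5% into 82% vs 18.5% into 18%)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def format_p(p: Optional[float]) -> str:
    if p is None or not math.isfinite(p):
        return "NC"  # not computable (degenerate variance)
    if p > 0.99:
        return ">.99"
    return f"{p:.2f}".lstrip("0")


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetentionSummary:
    enrolled: int
    lost: int
    percent: float          # raw 100 * lost / enrolled
    percent_display: float  # whole-percent, half-up

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.lost}/{self.enrolled} ({self.percent_display:g}%) lost to follow-up"


def retention_summary(flow) -> RetentionSummary:
    """Loss to follow-up over all enrolled participants."""
    enrolled = sum(flow.enrolled.values())
    if enrolled <= 0:
        raise ValueError("no enrolled participants")
    lost = sum(len(v) for v in flow.lost.values())
    pct = 100.0 * lost / enrolled
    return RetentionSummary(enrolled=enrolled, lost=lost, percent=pct,
                            percent_display=round_half_up(pct))


@dataclass(frozen=True)
class PrevalenceResult:
    condition: Condition
    numerator: int
    denominator: int
    percent: float  # 100 * num / den, 1 decimal


def prevalence(participants: Sequence[ParticipantRecord],
               visits: Sequence[VisitRecord],
               condition: Condition | str,
               arm: Arm | str | None = None,
               thresholds=None) -> PrevalenceResult:
    """Condition prevalence over the participants in scope.

    * ``anemia_lt10``: Hb < 10.0 g/dL at the baseline (antenatal) visit.
    * ``hdp``: any antenatal BP classification at YELLOW or above.
    * ``gdm``: any OGTT classification at YELLOW or above.

    ``arm`` restricts the denominator to one trial arm; the denominator is
    the number of in-scope participants.
    """
    condition = Condition(condition)
    if arm is not None:
        arm = Arm(arm)
        scoped = [p for p in participants if p.arm is arm]
    else:
        scoped = list(participants)
    if not scoped:
        raise ValueError("empty scope: no participants")
    ids = {p.participant_id for p in scoped}
    flagged: set[str] = set()
    for v in visits:
        if v.participant_id not in ids:
            continue
        if condition is Condition.anemia_lt10:
            if v.visit_type is VisitType.antenatal and v.hb < ANEMIA_HB_THRESHOLD:
                flagged.add(v.participant_id)
        elif condition is Condition.hdp:
            if (v.visit_type is VisitType.antenatal
                    and classify_bp(v.sbp, v.dbp, v.heart_rate, thresholds)
                    >= TrafficLight.YELLOW):
                flagged.add(v.participant_id)
        elif condition is Condition.gdm:
            if (v.ogtt_2h_glucose is not None
                    and classify_ogtt(v.ogtt_2h_glucose, thresholds)
                    >= TrafficLight.YELLOW):
                flagged.add(v.participant_id)
    num, den = len(flagged), len(scoped)
    return PrevalenceResult(condition=condition, numerator=num, denominator=den,
                            percent=round_half_up(100.0 * num / den, 1))


def expected_schedule(participants: Sequence[ParticipantRecord],
                      visit_types: Sequence[VisitType] = (
                          VisitType.antenatal, VisitType.postpartum_week1,
                          VisitType.postpartum_week6),
                      arm: Arm | None = None) -> list[tuple[str, VisitType]]:
    """Protocol-expected (participant, visit type) entries."""
    out = []
    for p in participants:
        if arm is not None and p.arm is not arm:
            continue
        for vt in visit_types:
            out.append((p.participant_id, vt))
    return out


def fidelity_summary(visits: Sequence[VisitRecord],
                     schedule: Sequence[tuple[str, VisitType]],
                     participants: Sequence[ParticipantRecord] | None = None) -> float:
    """Percent of scheduled entries that exist, are complete, and fall on
    time (flagged on-time AND, when participant dates are supplied, dated
    inside the protocol visit window)."""
    if not schedule:
        raise ValueError("schedule must be non-empty")
    by_participant = {p.participant_id: p for p in (participants or [])}
    found: dict[tuple[str, VisitType], VisitRecord] = {}
    for v in visits:
        found.setdefault((v.participant_id, v.visit_type), v)
    ok = 0
    for pid, vt in schedule:
        v = found.get((pid, vt))
        if v is None or not (v.entry_complete and v.entry_on_time):
            continue
        p = by_participant.get(pid)
        if p is not None:
            lo, hi = visit_window(vt, p.lmp_date, p.delivery_date)
            if not (lo <= v.visit_date <= hi):
                continue
        ok += 1
    return round_half_up(100.0 * ok / len(schedule), 2)


@dataclass(frozen=True)
class ScreeningSummary:
    n: int
    gdm_screened: int
    ogtt_done: int
    gdm_screened_percent: float  # raw
    ogtt_done_percent: float     # raw
    gdm_screened_percent_display: float  # whole-percent, half-up
    ogtt_done_percent_display: float


def screening_summary(participants: Sequence[ParticipantRecord],
                      visits: Sequence[VisitRecord]) -> ScreeningSummary:
    """ANC-practice coverage at recruitment, read from each participant's
    antenatal visit flags."""
    if not participants:
        raise ValueError("no participants")
    flags = {}
    for v in visits:
        if v.visit_type is VisitType.antenatal:
            flags.setdefault(v.participant_id, (v.gdm_screened, v.ogtt_done))
    n = len(participants)
    screened = sum(1 for p in participants if flags.get(p.participant_id, (False, False))[0])
    ogtt = sum(1 for p in participants if flags.get(p.participant_id, (False, False))[1])
    return ScreeningSummary(
        n=n, gdm_screened=screened, ogtt_done=ogtt,
        gdm_screened_percent=100.0 * screened / n,
        ogtt_done_percent=100.0 * ogtt / n,
        gdm_screened_percent_display=round_half_up(100.0 * screened / n),
        ogtt_done_percent_display=round_half_up(100.0 * ogtt / n),
    )


# ---------------------------------------------------------------------------
# arm comparison table


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    intervention_mean: float
    intervention_sd: float
    control_mean: float
    control_sd: float
    n_intervention: int
    n_control: int
    p_value: Optional[float]
    p_display: str


def _welch_p(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Two-sided Welch (unequal-variance) t-test p-value; None when both
    arms are degenerate. Isolated so a pooled-variance variant can be
    swapped in one place."""
    if len(a) < 2 or len(b) < 2:
        return None
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return None  # identical constants: no variance to test against
        return None
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def _visit_value(visits, pid_to_arm, visit_type, attr):
    a, b = [], []
    for v in visits:
        if v.visit_type is not visit_type:
            continue
        arm = pid_to_arm.get(v.participant_id)
        value = getattr(v, attr)
        if arm is None or value is None:
            continue
        (a if arm is Arm.intervention else b).append(float(value))
    return np.asarray(a), np.asarray(b)


def comparison_table(participants: Sequence[ParticipantRecord],
                     visits: Sequence[VisitRecord]) -> list[ComparisonRow]:
    """Baseline/end-line mean (SD) per arm with a two-sided Welch p-value
    per variable."""
    pid_to_arm = {p.participant_id: p.arm for p in participants}

    def part_arrays(fn):
        a = [fn(p) for p in participants if p.arm is Arm.intervention and fn(p) is not None]
        b = [fn(p) for p in participants if p.arm is Arm.control and fn(p) is not None]
        return np.asarray(a, dtype=float), np.asarray(b, dtype=float)

    spec: list[tuple[str, tuple[np.ndarray, np.ndarray]]] = [
        ("age_years", part_arrays(lambda p: age_years(p.date_of_birth, p.registration_date))),
        ("bmi", part_arrays(lambda p: bmi(p.weight, p.height))),
        ("schooling_years", part_arrays(lambda p: p.schooling_years)),
        ("household_size", part_arrays(lambda p: p.household_size)),
        ("booking_hb", part_arrays(lambda p: p.booking_hb)),
        ("baseline_hb", _visit_value(visits, pid_to_arm, VisitType.antenatal, "hb")),
        ("baseline_sbp", _visit_value(visits, pid_to_arm, VisitType.antenatal, "sbp")),
        ("baseline_dbp", _visit_value(visits, pid_to_arm, VisitType.antenatal, "dbp")),
        ("endline_hb", _visit_value(visits, pid_to_arm, VisitType.postpartum_week6, "hb")),
        ("endline_sbp", _visit_value(visits, pid_to_arm, VisitType.postpartum_week6, "sbp")),
        ("endline_dbp", _visit_value(visits, pid_to_arm, VisitType.postpartum_week6, "dbp")),
    ]
    rows = []
    for name, (a, b) in spec:
        if len(a) < 2 or len(b) < 2:
            continue
        p = _welch_p(a, b)
        rows.append(ComparisonRow(
            variable=name,
            intervention_mean=round(float(np.mean(a)), 1),
            intervention_sd=round(float(np.std(a, ddof=1)), 1),
            control_mean=round(float(np.mean(b)), 1),
            control_sd=round(float(np.std(b, ddof=1)), 1),
            n_intervention=len(a), n_control=len(b),
            p_value=p, p_display=format_p(p),
        ))
    return rows


# ---------------------------------------------------------------------------
# recruitment


@dataclass(frozen=True)
class RecruitmentCluster:
    cluster_id: str
    n_recruited: int
    days: Optional[int]            # first-to-last registration span
    rate_per_month: Optional[float]


def recruitment_summary(participants: Sequence[ParticipantRecord]) -> list[RecruitmentCluster]:
    """Per-cluster recruitment span and monthly rate (None when a cluster
    has fewer than 2 registrations or a zero-day span)."""
    by_cluster: dict[str, list] = {}
    for p in participants:
        by_cluster.setdefault(p.cluster_id, []).append(p.registration_date)
    out = []
    for cid in sorted(by_cluster):
        dates = by_cluster[cid]
        if len(dates) < 2:
            out.append(RecruitmentCluster(cid, len(dates), None, None))
            continue
        days = (max(dates) - min(dates)).days
        rate = None if days == 0 else round(len(dates) / (days / DAYS_PER_MONTH), 1)
        out.append(RecruitmentCluster(cid, len(dates), days, rate))
    return out


# ---------------------------------------------------------------------------
# combined summary


@dataclass
class TrialSummary:
    retention: RetentionSummary
    prevalence: dict = field(default_factory=dict)
    screening: Optional[ScreeningSummary] = None
    fidelity_percent: Optional[float] = None
    comparison: list = field(default_factory=list)
    recruitment: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retention": {
                "enrolled": self.retention.enrolled,
                "lost": self.retention.lost,
                "percent": self.retention.percent,
                "percent_display": self.retention.percent_display,
            },
            "prevalence": {
                key: {"numerator": r.numerator, "denominator": r.denominator,
                      "percent": r.percent}
                for key, r in self.prevalence.items()
            },
            "screening": None if self.screening is None else {
                "n": self.screening.n,
                "gdm_screened": self.screening.gdm_screened,
                "ogtt_done": self.screening.ogtt_done,
                "gdm_screened_percent": self.screening.gdm_screened_percent_display,
                "ogtt_done_percent": self.screening.ogtt_done_percent_display,
            },
            "fidelity_percent": self.fidelity_percent,
            "comparison": [
                {"variable": r.variable,
                 "intervention": f"{r.intervention_mean} ({r.intervention_sd})",
                 "control": f"{r.control_mean} ({r.control_sd})",
                 "n": [r.n_intervention, r.n_control],
                 "p": r.p_display}
                for r in self.comparison
            ],
            "recruitment": [
                {"cluster_id": r.cluster_id, "n": r.n_recruited,
                 "days": r.days, "rate_per_month": r.rate_per_month}
                for r in self.recruitment
            ],
        }


def summarize(participants: Sequence[ParticipantRecord],
              visits: Sequence[VisitRecord], flow,
              thresholds=None) -> TrialSummary:
    """Full trial summary mirroring the feasibility-report layout."""
    prev = {
        "hdp_all": prevalence(participants, visits, Condition.hdp, thresholds=thresholds),
        "gdm_all": prevalence(participants, visits, Condition.gdm, thresholds=thresholds),
        "anemia_intervention": prevalence(participants, visits,
                                          Condition.anemia_lt10, arm=Arm.intervention),
        "anemia_control": prevalence(participants, visits,
                                     Condition.anemia_lt10, arm=Arm.control),
    }
    schedule = expected_schedule(
        participants,
        visit_types=(VisitType.antenatal, VisitType.postpartum_week1),
        arm=Arm.intervention)
    fidelity = fidelity_summary(visits, schedule, participants) if schedule else None
    return TrialSummary(
        retention=retention_summary(flow),
        prevalence=prev,
        screening=screening_summary(participants, visits),
        fidelity_percent=fidelity,
        comparison=comparison_table(participants, visits),
        recruitment=recruitment_summary(participants),
    )


def format_summary(summary: TrialSummary) -> str:
    """Human-readable text table."""
    lines = []
    r = summary.retention
    lines.append(f"Retention: {r.lost}/{r.enrolled} lost to follow-up "
                 f"({r.percent_display:g}%)")
    for key, pr in summary.prevalence.items():
        lines.append(f"Prevalence [{key}]: {pr.numerator}/{pr.denominator} "
                     f"({pr.percent:g}%)")
    if summary.screening is not None:
        s = summary.screening
        lines.append(f"GDM screening: {s.gdm_screened}/{s.n} "
                     f"({s.gdm_screened_percent_display:g}%); "
                     f"OGTT done: {s.ogtt_done}/{s.n} "
                     f"({s.ogtt_done_percent_display:g}%)")
    if summary.fidelity_percent is not None:
        lines.append(f"Fidelity (intervention visits 1-2): {summary.fidelity_percent:g}%")
    if summary.comparison:
        lines.append("")
        lines.append(f"{'variable':<16}{'intervention':>16}{'control':>16}{'p':>8}")
        for row in summary.comparison:
            lines.append(
                f"{row.variable:<16}"
                f"{f'{row.intervention_mean} ({row.intervention_sd})':>16}"
                f"{f'{row.control_mean} ({row.control_sd})':>16}"
                f"{row.p_display:>8}")
    if summary.recruitment:
        lines.append("")
        for rc in summary.recruitment:
            rate = "NC" if rc.rate_per_month is None else f"{rc.rate_per_month:g}/month"
            days = "NC" if rc.days is None else f"{rc.days} days"
            lines.append(f"Recruitment [{rc.cluster_id}]: n={rc.n_recruited}, "
                         f"{days}, {rate}")
    return "\n".join(lines) + "\n"
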