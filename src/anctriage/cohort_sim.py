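"""Synthetic two-arm cluster-trial cohort generator.

Continuous variables are drawn from truncated normal distributions with
configured moments; dichotomised counts (anaemia, raised BP, GDM, screening
flags, loss to follow-up) are enforced EXACTLY by rank-based assignment, so
downstream percentage summaries recompute the configured numerators without
sampling noise. Deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.stats import truncnorm

from .records import (Arm, ParticipantRecord, VisitRecord, VisitType,
                      write_participants, write_visits)
from .rules_engine import ELIGIBLE_GA_MAX_DAYS, ELIGIBLE_GA_MIN_DAYS

__all__ = ["SimConfig", "TrialFlow", "default_config", "simulate_cohort", "write_cohort"]

ArmPair = Tuple[float, float]  # (intervention, control)
CountPair = Tuple[int, int]


class SimConfig(BaseModel):
    """Moments, counts and schedule parameters for the simulated trial.

    All paired fields are (intervention, control). Defaults are supplied by
    :func:`default_config`; counts must be feasible for the arm sizes.
    """

    n_per_arm: int = 100
    clusters_per_arm: int = 2
    state_labels: Tuple[str, ...] = ("HR", "AP")

    age_mean: ArmPair
    age_sd: ArmPair
    bmi_mean: ArmPair
    bmi_sd: ArmPair
    schooling_mean: ArmPair
    schooling_sd: ArmPair
    household_mean: ArmPair
    household_sd: ArmPair
    booking_hb_mean: ArmPair
    booking_hb_sd: ArmPair
    baseline_hb_mean: ArmPair
    baseline_hb_sd: ArmPair
    endline_hb_mean: ArmPair
    endline_hb_sd: ArmPair
    baseline_sbp_mean: ArmPair
    baseline_sbp_sd: ArmPair
    baseline_dbp_mean: ArmPair
    baseline_dbp_sd: ArmPair
    endline_sbp_mean: ArmPair
    endline_sbp_sd: ArmPair
    endline_dbp_mean: ArmPair
    endline_dbp_sd: ArmPair

    anemia_count: CountPair        # baseline-visit Hb < 10.0 g/dL, per arm
    hdp_count: CountPair           # antenatal BP >= YELLOW band, per arm
    gdm_count: CountPair           # antenatal OGTT >= YELLOW band, per arm
    ltfu_count: CountPair          # no end-line visit, per arm
    gdm_screened_count: CountPair  # ANC flag at recruitment, per arm
    ogtt_done_count: CountPair     # ANC flag at recruitment, per arm

    fidelity_fraction: float = 1.0
    # per cluster, ordered (int/HR, int/AP, ctl/HR, ctl/AP): first-to-last
    # registration span in days
    recruitment_days: Tuple[int, ...] = (50, 105, 80, 128)
    # optional pandemic gap: additional end-line records withheld per arm
    endline_missing_count: CountPair = (0, 0)
    study_start: date = date(2019, 10, 1)
    seed: int = 20230720

    @model_validator(mode="after")
    def _feasible(self) -> "SimConfig":
        n = self.n_per_arm
        for name in ("anemia_count", "hdp_count", "gdm_count", "ltfu_count",
                     "gdm_screened_count", "ogtt_done_count", "endline_missing_count"):
            pair = getattr(self, name)
            if any(c < 0 or c > n for c in pair):
                raise ValueError(f"{name} must be within [0, n_per_arm]")
        for name, value in self.model_dump().items():
            if name.endswith("_sd") and any(v <= 0 for v in value):
                raise ValueError(f"{name} entries must be positive")
        if not (0.0 <= self.fidelity_fraction <= 1.0):
            raise ValueError("fidelity_fraction must be in [0, 1]")
        if len(self.recruitment_days) != 2 * self.clusters_per_arm:
            raise ValueError("recruitment_days must have one entry per cluster")
        if any(o + l > n for o, l in zip(self.ogtt_done_count, self.ltfu_count)):
            pass  # flags and LTFU are independent subsets; no joint constraint
        return self


def default_config() -> SimConfig:
    """Defaults reproducing the pilot trial's printed baseline/end-line
    moments, condition counts, participant flow and practice-flag counts.

    Provenance (two equal arms of 100 across 4 primary-care clusters):
      * age 23.5 (3.5) / 24.0 (3.6) y; BMI 22.6 (4.0) / 22.1 (4.1) kg/m2;
        schooling 12.2 (3.7) / 12.4 (4.0) y; household 4.9 (2.1) / 4.8 (1.9)
      * Hb (g/dL): booking 9.6 (1.4) / 9.4 (1.4); baseline study visit
        9.9 (1.7) / 9.6 (1.7); end-line 11.1 (1.7) / 10.3 (1.7)
      * BP (mmHg): baseline 108/70 both arms (SDs 11.3-12.4, 8.5-9.0);
        end-line 110/72 vs 112/73
      * baseline anaemia (Hb<10): 47/100 intervention, 58/100 control
      * raised-BP cases 5/200 (split 3/2), GDM cases 4/200 (split 2/2)
      * lost to follow-up: 0 intervention, 4 control (2 per control cluster)
      * GDM screening flag 163/200 (split 82/81); prior OGTT 37/200 (19/18)
      * per-cluster recruitment spans 50-128 days; fidelity 1.0 prepandemic
    """
    return SimConfig(
        age_mean=(23.5, 24.0), age_sd=(3.5, 3.6),
        bmi_mean=(22.6, 22.1), bmi_sd=(4.0, 4.1),
        schooling_mean=(12.2, 12.4), schooling_sd=(3.7, 4.0),
        household_mean=(4.9, 4.8), household_sd=(2.1, 1.9),
        booking_hb_mean=(9.6, 9.4), booking_hb_sd=(1.4, 1.4),
        baseline_hb_mean=(9.9, 9.6), baseline_hb_sd=(1.7, 1.7),
        endline_hb_mean=(11.1, 10.3), endline_hb_sd=(1.7, 1.7),
        baseline_sbp_mean=(108.0, 108.0), baseline_sbp_sd=(11.3, 12.4),
        baseline_dbp_mean=(70.0, 70.0), baseline_dbp_sd=(8.5, 9.0),
        endline_sbp_mean=(110.0, 112.0), endline_sbp_sd=(11.6, 13.4),
        endline_dbp_mean=(72.0, 73.0), endline_dbp_sd=(8.2, 11.9),
        anemia_count=(47, 58),
        hdp_count=(3, 2),
        gdm_count=(2, 2),
        ltfu_count=(0, 4),
        gdm_screened_count=(82, 81),
        ogtt_done_count=(19, 18),
    )


@dataclass
class TrialFlow:
    """Participant accounting per arm: enrolled == completed + lost."""

    enrolled: dict = field(default_factory=dict)   # arm -> count
    completed: dict = field(default_factory=dict)  # arm -> count with end-line
    lost: dict = field(default_factory=dict)       # arm -> list of (id, reason)

    def to_dict(self) -> dict:
        return {
            "enrolled": dict(self.enrolled),
            "completed": dict(self.completed),
            "lost": {arm: [{"participant_id": pid, "reason": reason}
                           for pid, reason in entries]
                     for arm, entries in self.lost.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialFlow":
        return cls(
            enrolled={k: int(v) for k, v in d["enrolled"].items()},
            completed={k: int(v) for k, v in d["completed"].items()},
            lost={k: [(e["participant_id"], e["reason"]) for e in v]
                  for k, v in d["lost"].items()},
        )


# ---------------------------------------------------------------------------
# sampling helpers


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _enforce_count_below(values: np.ndarray, threshold: float, k: int,
                         step: float, lo: float, hi: float) -> np.ndarray:
    """Affine-shift ``values`` so that, after rounding to ``step``, exactly
    ``k`` of them fall strictly below ``threshold``. Rank order is
    preserved; boundary offenders after rounding are nudged by one step."""
    v = np.asarray(values, dtype=float).copy()
    n = len(v)
    if not 0 <= k <= n:
        raise ValueError("count out of range")
    order = np.argsort(v, kind="stable")
    if k == 0:
        shift = max(0.0, threshold - v.min() + step)
    elif k == n:
        shift = min(0.0, threshold - v.max() - step)
    else:
        vk0, vk1 = v[order[k - 1]], v[order[k]]
        shift = threshold - (vk0 + vk1) / 2.0
    v = v + shift
    decimals = max(0, int(round(-np.log10(step))))
    v = np.round(v, decimals)
    # rounding can push boundary values across the threshold; repair exactly
    low_idx = order[:k]
    high_idx = order[k:]
    v[low_idx] = np.minimum(v[low_idx], round(threshold - step, decimals))
    v[high_idx] = np.maximum(v[high_idx], threshold)
    return np.clip(v, lo, hi)


def _pick(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Boolean mask with exactly k True among n, uniformly at random."""
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


# ---------------------------------------------------------------------------
# generation


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None
                    ) -> tuple[list[ParticipantRecord], list[VisitRecord], TrialFlow]:
    """Generate participants, their three protocol visits, and the trial
    flow. ``seed`` overrides ``config.seed``."""
    config = config or default_config()
    run_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    id_prefix = f"P{run_seed % 1000:03d}"
    participants: list[ParticipantRecord] = []
    visits: list[VisitRecord] = []
    flow = TrialFlow()

    n = config.n_per_arm
    per_cluster = n // config.clusters_per_arm
    cluster_starts = [config.study_start + timedelta(days=21 * i)
                      for i in range(2 * config.clusters_per_arm)]

    pid_counter = 0
    for arm_idx, arm in enumerate((Arm.intervention, Arm.control)):
        # --- continuous variables, arm level
        ages = _tnorm(rng, config.age_mean[arm_idx], config.age_sd[arm_idx], 16, 45, n)
        bmis = _tnorm(rng, config.bmi_mean[arm_idx], config.bmi_sd[arm_idx], 13, 45, n)
        heights = _tnorm(rng, 1.56, 0.06, 1.40, 1.80, n)
        schooling = np.round(_tnorm(rng, config.schooling_mean[arm_idx],
                                    config.schooling_sd[arm_idx], 0, 20, n)).astype(int)
        household = np.round(_tnorm(rng, config.household_mean[arm_idx],
                                    config.household_sd[arm_idx], 1, 15, n)).astype(int)
        booking_hb = np.round(_tnorm(rng, config.booking_hb_mean[arm_idx],
                                     config.booking_hb_sd[arm_idx], 4.0, 16.0, n), 1)

        baseline_hb = _tnorm(rng, config.baseline_hb_mean[arm_idx],
                             config.baseline_hb_sd[arm_idx], 4.0, 16.0, n)
        baseline_hb = _enforce_count_below(baseline_hb, 10.0,
                                           config.anemia_count[arm_idx],
                                           step=0.1, lo=4.0, hi=16.0)
        endline_hb = np.round(_tnorm(rng, config.endline_hb_mean[arm_idx],
                                     config.endline_hb_sd[arm_idx], 4.0, 16.0, n), 1)

        # non-case vitals stay inside the green band; flagged cases are
        # placed inside the yellow band so colour-based prevalence
        # recomputation agrees with the configured labels
        hdp_mask = _pick(rng, n, config.hdp_count[arm_idx])
        gdm_mask = _pick(rng, n, config.gdm_count[arm_idx])
        sbp = np.round(_tnorm(rng, config.baseline_sbp_mean[arm_idx],
                              config.baseline_sbp_sd[arm_idx], 85, 139, n))
        dbp = np.round(_tnorm(rng, config.baseline_dbp_mean[arm_idx],
                              config.baseline_dbp_sd[arm_idx], 50, 89, n))
        dbp = np.minimum(dbp, sbp - 15)  # keep sbp > dbp physiological
        sbp[hdp_mask] = np.round(rng.uniform(141, 158, hdp_mask.sum()))
        dbp[hdp_mask] = np.round(rng.uniform(91, 105, hdp_mask.sum()))
        glucose = np.round(_tnorm(rng, 110.0, 15.0, 70, 139, n))
        glucose[gdm_mask] = np.round(rng.uniform(141, 198, gdm_mask.sum()))

        end_sbp = np.round(_tnorm(rng, config.endline_sbp_mean[arm_idx],
                                  config.endline_sbp_sd[arm_idx], 85, 139, n))
        end_dbp = np.round(_tnorm(rng, config.endline_dbp_mean[arm_idx],
                                  config.endline_dbp_sd[arm_idx], 50, 89, n))
        end_dbp = np.minimum(end_dbp, end_sbp - 15)
        week1_sbp = np.round(_tnorm(rng, config.endline_sbp_mean[arm_idx],
                                    config.endline_sbp_sd[arm_idx], 85, 139, n))
        week1_dbp = np.round(_tnorm(rng, config.endline_dbp_mean[arm_idx],
                                    config.endline_dbp_sd[arm_idx], 50, 89, n))
        week1_dbp = np.minimum(week1_dbp, week1_sbp - 15)
        week1_hb = np.round(_tnorm(rng, config.endline_hb_mean[arm_idx],
                                   config.endline_hb_sd[arm_idx], 4.0, 16.0, n), 1)

        screened_mask = _pick(rng, n, config.gdm_screened_count[arm_idx])
        # a prior OGTT implies prior screening where feasible
        ogtt_mask = np.zeros(n, dtype=bool)
        k_ogtt = config.ogtt_done_count[arm_idx]
        screened_idx = np.flatnonzero(screened_mask)
        if k_ogtt <= len(screened_idx):
            ogtt_mask[rng.choice(screened_idx, size=k_ogtt, replace=False)] = True
        else:
            ogtt_mask = _pick(rng, n, k_ogtt)
        ltfu_mask = _ltfu_mask(rng, n, per_cluster, config.ltfu_count[arm_idx],
                               config.clusters_per_arm)
        endline_missing_mask = _pick(rng, n, config.endline_missing_count[arm_idx])

        incomplete_mask = rng.random(n) > config.fidelity_fraction

        lost_entries = []
        for j in range(n):
            cluster_local = j // per_cluster if per_cluster else 0
            cluster_local = min(cluster_local, config.clusters_per_arm - 1)
            cluster_global = arm_idx * config.clusters_per_arm + cluster_local
            state = config.state_labels[cluster_local % len(config.state_labels)]
            cluster_id = f"PHC_{state}_{'I' if arm is Arm.intervention else 'C'}"
            pid = f"{id_prefix}_{pid_counter:04d}"
            pid_counter += 1

            # registration spread evenly across the cluster's recruitment span
            span = config.recruitment_days[cluster_global]
            pos = j % per_cluster if per_cluster else 0
            offset = round(pos * span / max(per_cluster - 1, 1))
            reg_date = cluster_starts[cluster_global] + timedelta(days=int(offset))

            ga_reg = int(rng.integers(ELIGIBLE_GA_MIN_DAYS, ELIGIBLE_GA_MAX_DAYS + 1))
            lmp = reg_date - timedelta(days=ga_reg)
            delivery = lmp + timedelta(days=280 + int(rng.integers(-10, 8)))
            dob = reg_date - timedelta(days=int(round(ages[j] * 365.2425))
                                       + int(rng.integers(0, 365)))

            height = float(np.round(heights[j], 3))
            weight = float(np.round(bmis[j] * height * height, 1))
            participants.append(ParticipantRecord(
                participant_id=pid, cluster_id=cluster_id, arm=arm,
                date_of_birth=dob, registration_date=reg_date,
                height=height, weight=weight, lmp_date=lmp,
                delivery_date=delivery, schooling_years=int(schooling[j]),
                household_size=int(household[j]), booking_hb=float(booking_hb[j]),
            ))

            flags = dict(gdm_screened=bool(screened_mask[j]),
                         ogtt_done=bool(ogtt_mask[j]),
                         ifa_supplied=True)
            complete = not bool(incomplete_mask[j])
            hr_base = _safe_heart_rate(rng, sbp[j])
            visits.append(VisitRecord(
                participant_id=pid, visit_type=VisitType.antenatal,
                visit_date=reg_date, sbp=float(sbp[j]), dbp=float(dbp[j]),
                heart_rate=hr_base, hb=float(baseline_hb[j]),
                ogtt_2h_glucose=float(glucose[j]),
                entry_complete=complete, entry_on_time=True, **flags))
            visits.append(VisitRecord(
                participant_id=pid, visit_type=VisitType.postpartum_week1,
                visit_date=delivery + timedelta(days=int(rng.integers(1, 7))),
                sbp=float(week1_sbp[j]), dbp=float(week1_dbp[j]),
                heart_rate=_safe_heart_rate(rng, week1_sbp[j]),
                hb=float(week1_hb[j]), ogtt_2h_glucose=None,
                entry_complete=complete, entry_on_time=True, **flags))
            if ltfu_mask[j]:
                lost_entries.append((pid, "moved out of study area"))
            elif not endline_missing_mask[j]:
                visits.append(VisitRecord(
                    participant_id=pid, visit_type=VisitType.postpartum_week6,
                    visit_date=delivery + timedelta(days=int(rng.integers(39, 46))),
                    sbp=float(end_sbp[j]), dbp=float(end_dbp[j]),
                    heart_rate=_safe_heart_rate(rng, end_sbp[j]),
                    hb=float(endline_hb[j]), ogtt_2h_glucose=None,
                    entry_complete=complete, entry_on_time=True, **flags))

        flow.enrolled[arm.value] = n
        flow.completed[arm.value] = n - len(lost_entries)
        flow.lost[arm.value] = lost_entries

    return participants, visits, flow


def _ltfu_mask(rng: np.random.Generator, n: int, per_cluster: int,
               k: int, clusters: int) -> np.ndarray:
    """Spread lost-to-follow-up cases evenly across the arm's clusters
    (the pilot lost 2 at each control site)."""
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return mask
    base, extra = divmod(k, clusters)
    for c in range(clusters):
        kc = base + (1 if c < extra else 0)
        lo, hi = c * per_cluster, min((c + 1) * per_cluster, n)
        if kc and hi > lo:
            idx = rng.choice(np.arange(lo, hi), size=min(kc, hi - lo), replace=False)
            mask[idx] = True
    return mask


def _safe_heart_rate(rng: np.random.Generator, sbp: float) -> float:
    """Heart rate with a shock index safely inside the green band."""
    hi = min(115.0, 0.9 * sbp - 2.0)
    hr = float(np.round(_tnorm(rng, 82.0, 9.0, 55.0, max(hi, 56.0), 1)[0]))
    return hr


def write_cohort(out_dir: str | Path,
                 participants: Sequence[ParticipantRecord],
                 visits: Sequence[VisitRecord],
                 flow: TrialFlow) -> dict[str, Path]:
    """Write participants.csv, visits.csv and flow.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "visits": out / "visits.csv",
        "flow": out / "flow.json",
    }
    write_participants(paths["participants"], participants)
    write_visits(paths["visits"], visits)
    paths["flow"].write_text(json.dumps(flow.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths
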