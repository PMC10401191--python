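"""Two-step validation of the rules engine against an independently coded
oracle: a 200-case clinical fixture covering every decision-table band, then
a large randomly generated case set (10,000 by default) spanning the full
valid ranges of every input, with boundary enrichment.

The oracle here is a deliberately separate implementation — an exhaustive
if/else decision tree written directly from the raw threshold config — that
shares nothing with :mod:`anctriage.rules_engine` beyond that config file.
Do not refactor the two onto common helpers: their independence is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._config import Thresholds, band_edges, load_raw_thresholds
from .derived import DomainError
from .rules_engine import TrafficLight, case_colors_and_codes

__all__ = [
    "ValidationCase",
    "CaseOutcome",
    "ValidationReport",
    "generate_clinical_fixture",
    "generate_random_cases",
    "oracle_assess",
    "engine_assess",
    "concordance",
    "mutation_check",
    "CLINICAL_FIXTURE_SIZE",
]

CLINICAL_FIXTURE_SIZE = 200

# full valid measurement ranges (matching record invariants)
_SBP_RANGE = (31, 300)
_DBP_MIN = 30
_HR_RANGE = (20, 250)
_HB_RANGE = (2.0, 20.0)
_GLU_RANGE = (30, 600)


@dataclass(frozen=True)
class ValidationCase:
    case_id: str
    sbp: float
    dbp: float
    heart_rate: float
    hb: float
    ogtt_2h_glucose: Optional[float] = None
    stratum: str = "random"


@dataclass(frozen=True)
class CaseOutcome:
    bp_color: TrafficLight
    hb_color: TrafficLight
    gdm_color: Optional[TrafficLight]
    overall_color: TrafficLight
    codes: tuple


@dataclass
class ValidationReport:
    n_cases: int
    n_concordant: int
    match_fraction: float
    discordances: list = field(default_factory=list)  # (case_id, engine, oracle)

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_concordant": self.n_concordant,
            "match_fraction": self.match_fraction,
            "discordances": [
                {
                    "case_id": cid,
                    "engine": _outcome_dict(e),
                    "oracle": _outcome_dict(o),
                }
                for cid, e, o in self.discordances
            ],
        }


def _outcome_dict(o: CaseOutcome) -> dict:
    return {
        "bp": o.bp_color.name,
        "hb": o.hb_color.name,
        "gdm": None if o.gdm_color is None else o.gdm_color.name,
        "overall": o.overall_color.name,
        "codes": list(o.codes),
    }


# ---------------------------------------------------------------------------
# case generation


def _edge_pools(raw: dict) -> dict[str, list[float]]:
    """Per-measurement pools of band-edge values and edge-minus-one-step
    values, used for boundary enrichment."""
    pools: dict[str, list[float]] = {"sbp": [], "dbp": [], "si": [], "hb": [], "glucose": []}
    for _, (kind, value, step) in band_edges(raw).items():
        pools[kind].append(round(value, 6))
        pools[kind].append(round(value - step, 6))
    return pools


def generate_random_cases(n: int, seed: int,
                          raw_thresholds: dict | None = None) -> list[ValidationCase]:
    """``n`` cases drawn uniformly over the full valid ranges, with 10%
    per-variable boundary enrichment (a variable is pinned exactly at a
    configured band edge, or one resolution step below it). Deterministic
    per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    raw = raw_thresholds or load_raw_thresholds()
    pools = _edge_pools(raw)
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        # shock-index enrichment pins the HR/SBP pair jointly
        if rng.random() < 0.1:
            sbp = 100.0
            hr = float(round(rng.choice(pools["si"]) * 100))
        else:
            if rng.random() < 0.1:
                sbp = float(rng.choice(pools["sbp"]))
            else:
                sbp = float(rng.integers(_SBP_RANGE[0], _SBP_RANGE[1] + 1))
            hr = float(rng.integers(_HR_RANGE[0], _HR_RANGE[1] + 1))
        dbp_candidates = [v for v in pools["dbp"] if v < sbp]
        if dbp_candidates and rng.random() < 0.1:
            dbp = float(rng.choice(dbp_candidates))
        else:
            dbp = float(rng.integers(_DBP_MIN, int(sbp)))
        if rng.random() < 0.1:
            hb = float(rng.choice(pools["hb"]))
        else:
            hb = round(float(rng.uniform(*_HB_RANGE)), 1)
        if rng.random() < 0.1:
            glucose: Optional[float] = None  # "not screened" path
        elif rng.random() < 0.1:
            glucose = float(rng.choice(pools["glucose"]))
        else:
            glucose = float(rng.integers(_GLU_RANGE[0], _GLU_RANGE[1] + 1))
        cases.append(ValidationCase(
            case_id=f"R{i:05d}", sbp=sbp, dbp=dbp, heart_rate=hr, hb=hb,
            ogtt_2h_glucose=glucose, stratum="random"))
    return cases


def _structured_strata(raw: dict) -> list[tuple[str, float, float, float, float, Optional[float]]]:
    """Hand-laid clinical scenarios hitting every band of every condition,
    including each edge and edge-minus-one-step, plus mixed-severity combos.
    Neutral background: 110/70 mmHg, HR 80, Hb 12.0, glucose 110."""
    bp, hb, og = raw["bp"], raw["hb"], raw["ogtt"]
    res = raw["resolution"]
    sy, sr = bp["sbp_yellow"], bp["sbp_red"]
    dy, dr = bp["dbp_yellow"], bp["dbp_red"]
    siy, sir = bp["si_yellow"], bp["si_red"]
    hr_, hrf, hy = hb["red_below"], hb["referral_below"], hb["yellow_below"]
    gy, gr = og["yellow_at"], og["red_at"]
    s = []  # (stratum, sbp, dbp, hr, hb, glucose)
    # systolic bands
    for v, tag in [(110, "green_mid"), (sy - res["bp"], "green_edge"), (sy, "yellow_edge"),
                   ((sy + sr) // 2, "yellow_mid"), (sr - res["bp"], "yellow_high"),
                   (sr, "red_edge"), (200, "red_mid"), (300, "red_max")]:
        s.append((f"bp_sbp_{tag}", float(v), 70.0, 80.0, 12.0, 110.0))
    # diastolic bands
    for v, tag in [(dy - res["bp"], "green_edge"), (dy, "yellow_edge"),
                   ((dy + dr) // 2, "yellow_mid"), (dr - res["bp"], "yellow_high"),
                   (dr, "red_edge"), (130, "red_mid")]:
        s.append((f"bp_dbp_{tag}", 135.0, float(v), 80.0, 12.0, 110.0))
    # shock-index bands (sbp pinned at 100 so the ratio is exact)
    for ratio, tag in [(0.67, "green_mid"), (siy - res["si"], "green_edge"),
                       (siy, "yellow_edge"), (1.2, "yellow_mid"),
                       (sir - res["si"], "yellow_high"), (sir, "red_edge"), (2.2, "red_mid")]:
        s.append((f"bp_si_{tag}", 100.0, 60.0, float(round(ratio * 100)), 12.0, 110.0))
    # haemoglobin bands
    for v, tag in [(2.0, "red_min"), (round(hr_ - res["hb"], 1), "red_edge"),
                   (hr_, "yellow_low_edge"), (8.5, "yellow_referral_mid"),
                   (round(hrf - res["hb"], 1), "yellow_referral_high"),
                   (hrf, "yellow_mild_edge"), (round(hy - res["hb"], 1), "yellow_high"),
                   (hy, "green_edge"), (13.5, "green_mid"), (20.0, "green_max")]:
        s.append((f"hb_{tag}", 110.0, 70.0, 80.0, float(v), 110.0))
    # OGTT bands (plus the not-screened outcome)
    for v, tag in [(30.0, "green_min"), (float(gy - res["glucose"]), "green_edge"),
                   (float(gy), "yellow_edge"), (170.0, "yellow_mid"),
                   (float(gr - res["glucose"]), "yellow_high"), (float(gr), "red_edge"),
                   (400.0, "red_mid"), (600.0, "red_max")]:
        s.append((f"ogtt_{tag}", 110.0, 70.0, 80.0, 12.0, v))
    s.append(("ogtt_not_screened", 110.0, 70.0, 80.0, 12.0, None))
    # mixed-severity combinations
    s += [
        ("combo_all_green", 110.0, 70.0, 78.0, 12.0, 110.0),
        ("combo_all_yellow", 150.0, 95.0, 80.0, 10.5, 150.0),
        ("combo_all_red", 170.0, 115.0, 80.0, 6.0, 250.0),
        ("combo_htn_red_only", 165.0, 100.0, 80.0, 12.0, 110.0),
        ("combo_anemia_htn_yellow", 150.0, 95.0, 80.0, 9.0, 110.0),
        ("combo_si_red_rest_green", 100.0, 60.0, 180.0, 12.0, 110.0),
        ("combo_gdm_yellow_only", 110.0, 70.0, 80.0, 12.0, 150.0),
        ("combo_red_anemia_not_screened", 110.0, 70.0, 80.0, 5.5, None),
    ]
    return s


def generate_clinical_fixture(seed: int,
                              raw_thresholds: dict | None = None) -> list[ValidationCase]:
    """Exactly 200 cases: a deterministic structured core covering every
    decision-table band (each boundary value and the value one resolution
    step below it), padded to 200 with seeded boundary-enriched random
    cases."""
    raw = raw_thresholds or load_raw_thresholds()
    structured = _structured_strata(raw)
    cases = [
        ValidationCase(case_id=f"C{i:03d}", sbp=sbp, dbp=dbp, heart_rate=hr,
                       hb=hbv, ogtt_2h_glucose=glu, stratum=stratum)
        for i, (stratum, sbp, dbp, hr, hbv, glu) in enumerate(structured)
    ]
    n_fill = CLINICAL_FIXTURE_SIZE - len(cases)
    if n_fill < 0:
        raise RuntimeError("structured strata exceed the fixture size")
    fill = generate_random_cases(n_fill, seed=seed ^ 0x5EED, raw_thresholds=raw)
    for j, c in enumerate(fill):
        cases.append(ValidationCase(
            case_id=f"C{len(structured) + j:03d}", sbp=c.sbp, dbp=c.dbp,
            heart_rate=c.heart_rate, hb=c.hb, ogtt_2h_glucose=c.ogtt_2h_glucose,
            stratum="random_fill"))
    return cases


# ---------------------------------------------------------------------------
# the two implementations under comparison


def engine_assess(case: ValidationCase,
                  raw_thresholds: dict | None = None) -> CaseOutcome:
    """Classify one case with the production rules engine."""
    raw = raw_thresholds or load_raw_thresholds()
    t = Thresholds.from_raw(raw)
    bp, hbc, gdm, overall, codes = case_colors_and_codes(
        case.sbp, case.dbp, case.heart_rate, case.hb, case.ogtt_2h_glucose, t)
    return CaseOutcome(bp, hbc, gdm, overall, codes)


def oracle_assess(case: ValidationCase,
                  raw_thresholds: dict | None = None) -> CaseOutcome:
    """Classify one case with the independently coded oracle: a flat,
    exhaustive decision tree reading the raw config directly.

    Intentionally long-hand; shares no classification code with the engine.
    """
    raw = raw_thresholds or load_raw_thresholds()
    cbp, chb, cog = raw["bp"], raw["hb"], raw["ogtt"]
    G, Y, R = TrafficLight.GREEN, TrafficLight.YELLOW, TrafficLight.RED

    if case.sbp is None or case.dbp is None or case.heart_rate is None:
        raise DomainError("sbp, dbp and heart_rate are all required")
    if case.sbp <= 0:
        raise DomainError("sbp must be positive for shock index")
    si = case.heart_rate / case.sbp

    # blood pressure / shock index
    if case.sbp >= cbp["sbp_red"]:
        bp_color = R
    else:
        if case.dbp >= cbp["dbp_red"]:
            bp_color = R
        else:
            if si >= cbp["si_red"]:
                bp_color = R
            else:
                if case.sbp >= cbp["sbp_yellow"]:
                    bp_color = Y
                else:
                    if case.dbp >= cbp["dbp_yellow"]:
                        bp_color = Y
                    else:
                        if si >= cbp["si_yellow"]:
                            bp_color = Y
                        else:
                            bp_color = G

    # haemoglobin
    if case.hb is None:
        raise DomainError("hb is required")
    if case.hb < chb["red_below"]:
        hb_color = R
    else:
        if case.hb < chb["yellow_below"]:
            hb_color = Y
        else:
            hb_color = G

    # OGTT
    if case.ogtt_2h_glucose is None:
        gdm_color = None
    else:
        if case.ogtt_2h_glucose >= cog["red_at"]:
            gdm_color = R
        else:
            if case.ogtt_2h_glucose >= cog["yellow_at"]:
                gdm_color = Y
            else:
                gdm_color = G

    # overall severity
    if bp_color is R or hb_color is R or gdm_color is R:
        overall = R
    else:
        if bp_color is Y or hb_color is Y or gdm_color is Y:
            overall = Y
        else:
            overall = G

    # recommendation codes: red items, then yellow, BP -> Hb -> GDM order
    codes: list[str] = []
    if bp_color is R:
        codes.append("HTN_SEVERE_URGENT")
    if hb_color is R:
        codes.append("ANEMIA_SEVERE_URGENT")
    if gdm_color is R:
        codes.append("DM_OVERT_URGENT")
    if bp_color is Y:
        codes.append("HTN_REFER")
    if hb_color is Y:
        if case.hb < chb["referral_below"]:
            codes.append("ANEMIA_MOD_REFER")
        else:
            codes.append("ANEMIA_MILD_COUNSEL")
    if gdm_color is Y:
        codes.append("GDM_REFER")

    return CaseOutcome(bp_color, hb_color, gdm_color, overall, tuple(codes))


# ---------------------------------------------------------------------------
# concordance


def concordance(cases: Sequence[ValidationCase],
                engine_thresholds: dict | None = None,
                oracle_thresholds: dict | None = None) -> ValidationReport:
    """Run both implementations on every case and report agreement.

    A case is concordant iff all per-condition colours, the overall colour
    and the recommendation-code sequence match. Discordance is data, not an
    error."""
    if not cases:
        raise ValueError("case set must be non-empty")
    raw_engine = engine_thresholds or load_raw_thresholds()
    raw_oracle = oracle_thresholds if oracle_thresholds is not None else raw_engine
    discordances = []
    for case in cases:
        e = engine_assess(case, raw_engine)
        o = oracle_assess(case, raw_oracle)
        if e != o:
            discordances.append((case.case_id, e, o))
    n = len(cases)
    n_ok = n - len(discordances)
    return ValidationReport(n_cases=n, n_concordant=n_ok,
                            match_fraction=n_ok / n, discordances=discordances)


def mutation_check(cases: Sequence[ValidationCase],
                   raw_thresholds: dict | None = None) -> dict[str, bool]:
    """For every band edge, perturb it by one resolution step in each
    direction in the ORACLE's copy of the config and record whether at least
    one discordance appears. All values should be True on a
    boundary-enriched case set."""
    from ._config import perturb_threshold

    raw = raw_thresholds or load_raw_thresholds()
    results: dict[str, bool] = {}
    for key, (_, _, step) in band_edges(raw).items():
        for sign in (+1, -1):
            mutated = perturb_threshold(raw, key, sign * step)
            report = concordance(cases, engine_thresholds=raw, oracle_thresholds=mutated)
            results[f"{key}{'+' if sign > 0 else '-'}{step}"] = report.match_fraction < 1.0
    return results
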