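from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

from anctriage.cohort_sim import TrialFlow
from anctriage.records import Arm, ParticipantRecord, VisitType
from anctriage.trial_metrics import (Condition, comparison_table,
                                     expected_schedule, fidelity_summary,
                                     format_p, prevalence, recruitment_summary,
                                     retention_summary, round_half_up,
                                     screening_summary, summarize,
                                     _welch_p)

from conftest import make_visit


def _flow(lost_control=4, n=100):
    return TrialFlow(
        enrolled={"intervention": n, "control": n},
        completed={"intervention": n, "control": n - lost_control},
        lost={"intervention": [],
              "control": [(f"L{i}", "moved") for i in range(lost_control)]})


class TestRetention:
    def test_4_of_200_is_2_percent(self):
        r = retention_summary(_flow())
        assert (r.lost, r.enrolled) == (4, 200)
        assert r.percent == 2.0 and r.percent_display == 2.0

    def test_zero_lost(self):
        assert retention_summary(_flow(lost_control=0)).percent == 0.0

    def test_all_lost(self):
        flow = TrialFlow(enrolled={"control": 200}, completed={"control": 0},
                         lost={"control": [(f"L{i}", "x") for i in range(200)]})
        assert retention_summary(flow).percent == 100.0

    def test_zero_enrolled_errors(self):
        with pytest.raises(ValueError):
            retention_summary(TrialFlow(enrolled={}, completed={}, lost={}))


class TestPrevalence:
    def test_defaults_match_configured_counts(self, default_cohort):
        participants, visits, _ = default_cohort
        assert prevalence(participants, visits, Condition.anemia_lt10,
                          arm=Arm.intervention).percent == 47.0
        assert prevalence(participants, visits, Condition.anemia_lt10,
                          arm=Arm.control).percent == 58.0
        hdp = prevalence(participants, visits, Condition.hdp)
        assert (hdp.numerator, hdp.denominator, hdp.percent) == (5, 200, 2.5)
        gdm = prevalence(participants, visits, Condition.gdm)
        assert (gdm.numerator, gdm.denominator, gdm.percent) == (4, 200, 2.0)

    def test_zero_flagged_cases(self, participant):
        v = make_visit()
        assert prevalence([participant], [v], Condition.hdp).percent == 0.0

    def test_empty_scope_errors(self):
        with pytest.raises(ValueError):
            prevalence([], [], Condition.hdp)


class TestFidelity:
    def test_default_cohort_is_100(self, default_cohort):
        participants, visits, _ = default_cohort
        schedule = expected_schedule(
            participants, (VisitType.antenatal, VisitType.postpartum_week1),
            arm=Arm.intervention)
        assert len(schedule) == 200
        assert fidelity_summary(visits, schedule, participants) == 100.0

    def test_one_missing_among_300(self, default_cohort):
        participants, visits, _ = default_cohort
        schedule = expected_schedule(
            participants, (VisitType.antenatal, VisitType.postpartum_week1))[:300]
        drop_pid, drop_vt = schedule[0]
        kept = [v for v in visits
                if not (v.participant_id == drop_pid and v.visit_type is drop_vt)]
        assert fidelity_summary(kept, schedule, participants) == pytest.approx(
            99.67, abs=0.01)  # 299/300

    def test_no_visits_is_zero(self, default_cohort):
        participants, _, _ = default_cohort
        schedule = expected_schedule(participants)
        assert fidelity_summary([], schedule, participants) == 0.0

    def test_empty_schedule_errors(self):
        with pytest.raises(ValueError):
            fidelity_summary([], [])

    def test_out_of_window_visit_not_counted(self, participant):
        late = make_visit(visit_date=date(2020, 10, 20))  # past antenatal window
        schedule = [(participant.participant_id, VisitType.antenatal)]
        assert fidelity_summary([late], schedule, [participant]) == 0.0


class TestScreening:
    def test_default_cohort_percentages(self, default_cohort):
        participants, visits, _ = default_cohort
        s = screening_summary(participants, visits)
        assert (s.gdm_screened, s.ogtt_done) == (163, 37)
        # 163/200 = 81.5 and 37/200 = 18.5 display half-up as the printed 82/19
        assert s.gdm_screened_percent_display == 82.0
        assert s.ogtt_done_percent_display == 19.0

    def test_all_flags_true(self, participant):
        v = make_visit()
        s = screening_summary([participant], [v])
        assert s.gdm_screened_percent == 100.0 and s.ogtt_done_percent == 100.0

    def test_all_flags_false(self, participant):
        v = make_visit(gdm_screened=False, ogtt_done=False)
        s = screening_summary([participant], [v])
        assert s.gdm_screened_percent == 0.0 and s.ogtt_done_percent == 0.0


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (81.5, 82.0), (18.5, 19.0), (2.0, 2.0), (2.4, 2.0), (2.5, 3.0)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    @pytest.mark.parametrize("p,display", [
        (1.0, ">.99"), (0.995, ">.99"), (0.32, ".32"), (0.01, ".01"),
        (None, "NC"), (float("nan"), "NC")])
    def test_p_display(self, p, display):
        assert format_p(p) == display


class TestComparisonTable:
    def test_identical_arms_display_gt99(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        p = _welch_p(a, a.copy())
        assert format_p(p) == ">.99"

    def test_degenerate_variance_not_computable(self):
        p = _welch_p(np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0]))
        assert p is None and format_p(p) == "NC"

    def test_null_p_values_uniform(self):
        """1,000 same-distribution replicates: Welch p ~ U(0,1) (KS check)."""
        rng = np.random.default_rng(2024)
        ps = [_welch_p(rng.normal(10, 2, 50), rng.normal(10, 2, 50))
              for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_label_swap_invariance(self, default_cohort):
        participants, visits, _ = default_cohort
        swapped = [p.model_copy(update={"arm": Arm.control if p.arm is Arm.intervention
                                        else Arm.intervention})
                   for p in participants]
        rows = {r.variable: r for r in comparison_table(participants, visits)}
        rows_sw = {r.variable: r for r in comparison_table(swapped, visits)}
        for name, row in rows.items():
            assert row.p_value == pytest.approx(rows_sw[name].p_value, rel=1e-12)
            assert row.intervention_mean == rows_sw[name].control_mean

    def test_default_cohort_rows(self, default_cohort):
        participants, visits, _ = default_cohort
        rows = {r.variable: r for r in comparison_table(participants, visits)}
        assert set(rows) >= {"age_years", "bmi", "baseline_hb", "endline_hb",
                             "baseline_sbp", "baseline_dbp"}
        # configured moments recovered to table precision
        assert rows["bmi"].intervention_mean == pytest.approx(22.6, abs=1.3)
        assert rows["endline_hb"].n_control == 96  # 4 LTFU


class TestRecruitment:
    def _participants(self, dates, cluster="PHC_X"):
        out = []
        for i, d in enumerate(dates):
            out.append(ParticipantRecord(
                participant_id=f"P{i}", cluster_id=cluster, arm=Arm.control,
                date_of_birth=date(1995, 1, 1), registration_date=d,
                height=1.6, weight=60.0, lmp_date=d - timedelta(days=200),
                schooling_years=10, household_size=4))
        return out

    def test_span_days(self):
        start = date(2019, 10, 1)
        parts = self._participants([start + timedelta(days=int(x))
                                    for x in np.linspace(0, 50, 50)])
        (cluster,) = recruitment_summary(parts)
        assert cluster.days == 50

    def test_monthly_rate(self):
        start = date(2019, 10, 1)
        parts = self._participants([start + timedelta(days=int(x))
                                    for x in np.linspace(0, 91, 50)])
        (cluster,) = recruitment_summary(parts)
        # 50 / (91 / 30.44) = 16.7 per month
        assert cluster.rate_per_month == pytest.approx(16.7, abs=0.05)

    def test_single_day_cluster_not_computable(self):
        parts = self._participants([date(2019, 10, 1)] * 5)
        (cluster,) = recruitment_summary(parts)
        assert cluster.days == 0 and cluster.rate_per_month is None

    def test_single_registration_not_computable(self):
        (cluster,) = recruitment_summary(self._participants([date(2019, 10, 1)]))
        assert cluster.days is None and cluster.rate_per_month is None


class TestSummarize:
    def test_full_summary_dict(self, default_cohort):
        participants, visits, flow = default_cohort
        d = summarize(participants, visits, flow).to_dict()
        assert d["retention"]["percent_display"] == 2.0
        assert d["prevalence"]["hdp_all"]["percent"] == 2.5
        assert d["prevalence"]["gdm_all"]["percent"] == 2.0
        assert d["prevalence"]["anemia_intervention"]["percent"] == 47.0
        assert d["prevalence"]["anemia_control"]["percent"] == 58.0
        assert d["screening"]["gdm_screened_percent"] == 82.0
        assert d["screening"]["ogtt_done_percent"] == 19.0
        assert d["fidelity_percent"] == 100.0
        assert len(d["recruitment"]) == 4
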