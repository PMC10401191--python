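import itertools
from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from anctriage._config import ConfigError, load_raw_thresholds
from anctriage.derived import DomainError
from anctriage.records import VisitType
from anctriage.rules_engine import (TrafficLight, assess_visit, classify_bp,
                                    classify_hb, classify_ogtt,
                                    case_colors_and_codes, enrolment_eligible,
                                    visit_window)

from conftest import make_visit

G, Y, R = TrafficLight.GREEN, TrafficLight.YELLOW, TrafficLight.RED


class TestClassifyBp:
    def test_all_normal(self):
        assert classify_bp(120, 76, 80) is G  # SI 0.67

    def test_severe_hypertension_red(self):
        assert classify_bp(165, 100, 80) is R

    def test_shock_index_yellow(self):
        assert classify_bp(100, 60, 95) is Y  # SI 0.95

    @pytest.mark.parametrize("sbp,dbp,hr,expected", [
        (139, 70, 80, G), (140, 70, 80, Y), (159, 70, 80, Y), (160, 70, 80, R),
        (120, 89, 80, G), (120, 90, 80, Y), (130, 109, 80, Y), (130, 110, 80, R),
        (100, 60, 89, G), (100, 60, 90, Y), (100, 60, 169, Y), (100, 60, 170, R),
    ])
    def test_band_edges_lower_inclusive(self, sbp, dbp, hr, expected):
        assert classify_bp(sbp, dbp, hr) is expected

    def test_worst_band_applies(self):
        # sbp green but SI red
        assert classify_bp(100, 60, 180) is R

    def test_missing_input_is_error_not_green(self):
        with pytest.raises(DomainError):
            classify_bp(None, 70, 80)

    @given(sbp=st.integers(60, 290), dbp=st.integers(30, 59), hr=st.integers(20, 250),
           bump=st.integers(1, 10))
    def test_monotone_in_sbp_at_fixed_si(self, sbp, dbp, hr, bump):
        # raising sbp lowers SI, so fix SI by scaling hr with sbp
        lo = classify_bp(sbp, dbp, 0.5 * sbp)
        hi = classify_bp(sbp + bump, dbp, 0.5 * (sbp + bump))
        assert hi >= lo

    @given(sbp=st.integers(120, 300), dbp=st.integers(30, 110), hr=st.integers(20, 100),
           bump=st.integers(1, 30))
    def test_monotone_in_dbp(self, sbp, dbp, hr, bump):
        if dbp + bump >= sbp:
            return
        assert classify_bp(sbp, dbp + bump, hr) >= classify_bp(sbp, dbp, hr)


class TestClassifyHb:
    @pytest.mark.parametrize("hb,expected", [
        (11.5, G), (11.0, G), (10.9, Y), (10.0, Y), (9.9, Y), (7.0, Y),
        (6.9, R), (2.0, R),
    ])
    def test_bands(self, hb, expected):
        assert classify_hb(hb) is expected

    def test_missing_errors(self):
        with pytest.raises(DomainError):
            classify_hb(None)

    @given(hb=st.floats(2.0, 19.0), drop=st.floats(0.1, 5.0))
    def test_monotone_decreasing(self, hb, drop):
        if hb - drop < 2.0:
            return
        assert classify_hb(hb - drop) >= classify_hb(hb)


class TestClassifyOgtt:
    @pytest.mark.parametrize("glucose,expected", [
        (120, G), (139, G), (140, Y), (199, Y), (200, R), (600, R),
    ])
    def test_bands(self, glucose, expected):
        assert classify_ogtt(glucose) is expected

    def test_missing_is_not_a_color(self):
        with pytest.raises(DomainError):
            classify_ogtt(None)

    @given(g=st.integers(30, 570), bump=st.integers(1, 30))
    def test_monotone(self, g, bump):
        assert classify_ogtt(g + bump) >= classify_ogtt(g)


class TestAssessVisit:
    def test_all_normal_overall_green_no_referrals(self, participant):
        v = make_visit(sbp=110, dbp=70, heart_rate=78, hb=12.0, ogtt_2h_glucose=110)
        a = assess_visit(participant, v)
        assert a.overall_color is G
        assert a.recommendations == ()
        assert a.missing_practices == ()

    def test_two_yellow_conditions_compose(self, participant):
        v = make_visit(sbp=150, dbp=95, hb=9.0)
        a = assess_visit(participant, v)
        assert a.overall_color is Y
        codes = [r.code for r in a.recommendations]
        assert codes == ["HTN_REFER", "ANEMIA_MOD_REFER"]

    def test_red_puts_urgent_referral_first(self, participant, catalogue):
        v = make_visit(sbp=170, dbp=112, hb=12.0)
        a = assess_visit(participant, v)
        assert a.overall_color is R
        assert a.recommendations[0].code == "HTN_SEVERE_URGENT"
        assert a.recommendations[0].text == (
            "This woman has evidence of severe hypertension. "
            "Call ambulance and refer patient to hospital urgently.")

    def test_overall_is_max_severity_exhaustive_grid(self, participant):
        rep = {G: dict(sbp=110, dbp=70, heart_rate=78),
               Y: dict(sbp=150, dbp=95, heart_rate=78),
               R: dict(sbp=170, dbp=112, heart_rate=78)}
        hb_rep = {G: 12.0, Y: 10.5, R: 6.0}
        glu_rep = {G: 110.0, Y: 150.0, R: 250.0}
        for cb, ch, cg in itertools.product([G, Y, R], repeat=3):
            v = make_visit(hb=hb_rep[ch], ogtt_2h_glucose=glu_rep[cg], **rep[cb])
            a = assess_visit(participant, v)
            assert (a.bp_color, a.hb_color, a.gdm_color) == (cb, ch, cg)
            assert a.overall_color == max(cb, ch, cg)
            if R in (cb, ch, cg):
                assert any(r.code.endswith("_URGENT") for r in a.recommendations)

    def test_missing_ogtt_flags_practice(self, participant):
        v = make_visit(ogtt_2h_glucose=None, ogtt_done=False, gdm_screened=False)
        a = assess_visit(participant, v)
        assert a.gdm_color is None
        assert set(a.missing_practices) == {"gdm_not_screened", "ogtt_missing"}
        codes = [r.code for r in a.recommendations]
        assert codes == ["PROMPT_GDM_SCREEN", "PROMPT_OGTT"]

    def test_week6_missing_repeat_ogtt(self, participant):
        v = make_visit(visit_type=VisitType.postpartum_week6,
                       visit_date=date(2020, 11, 12), ogtt_2h_glucose=None)
        a = assess_visit(participant, v)
        assert "repeat_ogtt_missing" in a.missing_practices

    def test_wrong_participant_errors(self, participant):
        v = make_visit(participant_id="OTHER")
        with pytest.raises(DomainError):
            assess_visit(participant, v)


class TestTotality:
    @given(sbp=st.integers(31, 300), dbp=st.integers(30, 299),
           hr=st.integers(20, 250),
           hb=st.floats(2.0, 20.0).map(lambda x: round(x, 1)),
           glucose=st.one_of(st.none(), st.integers(30, 600)))
    def test_every_valid_input_gets_exactly_one_color(self, sbp, dbp, hr, hb, glucose):
        if dbp >= sbp:
            return
        bp, hbc, gdm, overall, _ = case_colors_and_codes(sbp, dbp, hr, hb, glucose)
        assert bp in (G, Y, R) and hbc in (G, Y, R)
        assert gdm in (G, Y, R, None)
        assert overall == max(c for c in (bp, hbc, gdm) if c is not None)


class TestEligibilityAndWindows:
    @pytest.mark.parametrize("ga,expected", [
        (195, False), (196, True), (258, True), (259, False),
    ])
    def test_enrolment_window(self, ga, expected):
        assert enrolment_eligible(ga) is expected

    def test_antenatal_window(self):
        assert visit_window(VisitType.antenatal, date(2020, 1, 1)) == (
            date(2020, 7, 15), date(2020, 9, 15))

    def test_week1_window(self):
        assert visit_window(VisitType.postpartum_week1, date(2020, 1, 1),
                            date(2020, 10, 1)) == (date(2020, 10, 1), date(2020, 10, 8))

    @given(offset=st.integers(0, 3000))
    def test_week6_window_contains_day42(self, offset):
        from datetime import timedelta
        d = date(2018, 1, 1) + timedelta(days=offset)
        lo, hi = visit_window(VisitType.postpartum_week6, d - timedelta(days=280), d)
        assert lo <= d + timedelta(days=42) <= hi

    def test_postpartum_without_delivery_errors(self):
        with pytest.raises(DomainError):
            visit_window(VisitType.postpartum_week1, date(2020, 1, 1), None)


class TestConfigContract:
    def test_engine_refuses_incomplete_config(self, tmp_path, raw_thresholds):
        import yaml
        broken = {k: dict(v) if isinstance(v, dict) else v
                  for k, v in raw_thresholds.items()}
        del broken["bp"]["si_red"]
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(broken))
        with pytest.raises(ConfigError, match="si_red"):
            load_raw_thresholds(path)

    def test_catalogue_requires_urgent_htn_code(self, tmp_path):
        from anctriage._config import load_recommendations
        path = tmp_path / "cat.yaml"
        path.write_text("SOMETHING_ELSE: hello\n")
        with pytest.raises(ConfigError, match="HTN_SEVERE_URGENT"):
            load_recommendations(path)
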