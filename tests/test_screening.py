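import math

import numpy as np
import pytest

from conftest import make_woman
from mammosim.natural_history import TumorHistory
from mammosim.rng import substream
from mammosim.screening import (
    NO_SCREENING,
    PerformanceTable,
    ScreeningStrategy,
    build_schedule,
    first_detection,
    interval_class,
    perform_screen,
)


def make_tumor(onset=60.0, clinical=65.0, subtype="ER+/HER2-"):
    return TumorHistory(
        has_tumor=True,
        clinical_detection_age=clinical,
        sojourn_years=clinical - onset,
        preclinical_onset_age=onset,
        subtype=subtype,
    )


class TestStrategy:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ScreeningStrategy("bad", ((50, 74, 2), (60, 80, 1)))

    def test_reversed_segment_rejected(self):
        with pytest.raises(ValueError, match="start"):
            ScreeningStrategy("bad", ((74, 50, 2),))


class TestBuildSchedule:
    def test_biennial_50_74(self):
        s = ScreeningStrategy.uniform(50, 74, 2)
        ages = build_schedule(s, make_woman(death_age=90))
        assert ages == [50 + 2 * k for k in range(13)]

    def test_hybrid_annual_then_biennial(self):
        # annual 45-54, then biennial 55-74 -> 45..54 then 56, 58, ..., 74
        s = ScreeningStrategy("hybrid", ((45, 54, 1), (55, 74, 2)))
        ages = build_schedule(s, make_woman(death_age=90))
        assert ages[:10] == [45 + k for k in range(10)]
        assert ages[10:] == [56 + 2 * k for k in range(10)]
        assert len(ages) == 20

    def test_one_time_truncated_by_death(self):
        s = ScreeningStrategy.one_time(50)
        assert build_schedule(s, make_woman(death_age=49)) == []
        assert build_schedule(s, make_woman(death_age=51)) == [50.0]

    def test_death_truncation_mid_schedule(self):
        s = ScreeningStrategy.uniform(50, 74, 2)
        ages = build_schedule(s, make_woman(death_age=61))
        assert ages == [50, 52, 54, 56, 58, 60]

    def test_no_screening_empty(self):
        assert build_schedule(NO_SCREENING, make_woman()) == []

    def test_empirical_dissemination_thins(self):
        s = ScreeningStrategy(
            "emp",
            ((50, 74, 2),),
            dissemination={"mode": "empirical", "first_age_offsets": [(0.0, 1.0)], "attendance": 0.5},
        )
        stream = substream(1, "attend")
        full = build_schedule(ScreeningStrategy.uniform(50, 74, 2), make_woman(death_age=90))
        thinned = build_schedule(s, make_woman(death_age=90), stream)
        assert set(thinned) <= set(full)
        assert 0 < len(thinned) < len(full)

    def test_empirical_requires_stream(self):
        s = ScreeningStrategy(
            "emp", ((50, 74, 2),), dissemination={"mode": "empirical", "first_age_offsets": [(0, 1.0)], "attendance": 1}
        )
        with pytest.raises(ValueError, match="stream"):
            build_schedule(s, make_woman())


class TestIntervalClass:
    @pytest.mark.parametrize(
        "gap,expected",
        [(None, "triennial"), (1.0, "annual"), (1.4, "annual"), (2.0, "biennial"), (2.4, "biennial"), (3.0, "triennial")],
    )
    def test_mapping(self, gap, expected):
        assert interval_class(gap) == expected


class TestPerformScreen:
    def test_perfect_sensitivity(self, rng):
        perf = PerformanceTable.constant(1.0, 0.9)
        w, t = make_woman(), make_tumor()
        for _ in range(50):
            ev = perform_screen(w, t, 62.0, perf, rng, first=True, gap_years=None)
            assert ev.result == "true_positive"

    def test_perfect_specificity(self, rng):
        perf = PerformanceTable.constant(0.8, 1.0)
        w = make_woman()
        for _ in range(50):
            ev = perform_screen(w, None, 62.0, perf, rng, first=True, gap_years=None)
            assert ev.result == "true_negative"

    def test_sensitivity_bernoulli(self, rng):
        perf = PerformanceTable.constant(0.8, 0.9)
        w, t = make_woman(), make_tumor()
        n = 10_000
        hits = sum(
            perform_screen(w, t, 62.0, perf, rng, first=False, gap_years=2.0).result == "true_positive"
            for _ in range(n)
        )
        se = math.sqrt(0.8 * 0.2 / n)
        assert hits / n == pytest.approx(0.8, abs=3 * se)

    def test_outside_window_is_negative_or_false_positive(self, rng):
        perf = PerformanceTable.constant(0.8, 0.9)
        w, t = make_woman(), make_tumor(onset=60, clinical=65)
        for age in (59.9, 65.0, 70.0):
            ev = perform_screen(w, t, age, perf, rng, first=True, gap_years=None)
            assert ev.result in ("false_positive", "true_negative")

    def test_biopsy_only_on_false_positive(self, rng):
        perf = PerformanceTable.constant(0.8, 0.0)
        w = make_woman()
        evs = [
            perform_screen(w, None, 55.0, perf, rng, first=True, gap_years=None, biopsy_prob=1.0)
            for _ in range(50)
        ]
        assert all(e.result == "false_positive" and e.led_to_biopsy for e in evs)


class TestFirstDetection:
    def test_empty_schedule_clinical(self):
        w, t = make_woman(death_age=90), make_tumor(clinical=65)
        det = first_detection(w, t, [], PerformanceTable.constant(1, 1), seed=1)
        assert det.mode == "clinical" and det.age == 65.0

    def test_latent_after_death_no_diagnosis(self):
        w, t = make_woman(death_age=60), make_tumor(onset=58, clinical=65)
        det = first_detection(w, t, [], PerformanceTable.constant(1, 1), seed=1)
        assert det.mode is None and det.age is None

    def test_zero_sensitivity_equals_no_screening(self, default_params):
        perf0 = PerformanceTable.constant(0.0, 1.0)
        for wid in range(100):
            w = make_woman(wid=wid, death_age=90)
            t = make_tumor()
            schedule = [50.0 + 2 * k for k in range(13)]
            with_screens = first_detection(w, t, schedule, perf0, seed=4)
            without = first_detection(w, t, [], perf0, seed=4)
            assert (with_screens.mode, with_screens.age) == (without.mode, without.age)

    def test_screen_at_onset_detects_with_lead_time(self):
        w, t = make_woman(death_age=90), make_tumor(onset=60, clinical=65)
        det = first_detection(w, t, [60.01], PerformanceTable.constant(1.0, 1.0), seed=2)
        assert det.mode == "screen"
        assert det.age == pytest.approx(60.01)
        assert det.age < t.clinical_detection_age

    def test_interval_cancer_flag(self):
        # sensitivity 0: every in-window screen is a false negative, then
        # the clinical detection is an interval cancer
        w, t = make_woman(death_age=90), make_tumor(onset=60, clinical=65)
        det = first_detection(w, t, [61.0, 63.0], PerformanceTable.constant(0.0, 1.0), seed=2)
        assert det.mode == "clinical" and det.interval_cancer

    def test_lead_time_bounded_by_sojourn(self, flat_performance):
        count = 0
        for wid in range(500):
            w = make_woman(wid=wid, death_age=95)
            t = make_tumor(onset=58.5, clinical=63.0)
            det = first_detection(w, t, [50 + 2 * k for k in range(13)], flat_performance, seed=6)
            if det.mode == "screen":
                lead = t.clinical_detection_age - det.age
                assert 0 < lead <= t.sojourn_years
                count += 1
        assert count > 0

    def test_expected_false_positives_toy_case(self):
        # no tumor, 3 screens, spec 0.9 -> E[FP] = 3 * 0.1
        perf = PerformanceTable.constant(0.8, 0.9)
        n = 5000
        total = 0
        for wid in range(n):
            w = make_woman(wid=wid, death_age=90)
            det = first_detection(w, None, [50.0, 52.0, 54.0], perf, seed=8)
            total += sum(e.result == "false_positive" for e in det.events)
        target = 3 * 0.1
        se = math.sqrt(3 * 0.1 * 0.9 / n)
        assert total / n == pytest.approx(target, abs=3 * se)


class TestNestedSchedules:
    """Annual contains biennial (aligned ages); shared per-age draws with an
    interval-independent performance table make detections nested."""

    def test_monotone_counts(self, flat_performance):
        annual = [50.0 + k for k in range(25)]
        biennial = [50.0 + 2 * k for k in range(13)]
        n_det_a = n_det_b = 0
        for wid in range(600):
            w = make_woman(wid=wid, death_age=95)
            t = make_tumor(onset=61.3, clinical=64.1) if wid % 2 else None
            det_a = first_detection(w, t, annual, flat_performance, seed=10)
            det_b = first_detection(w, t, biennial, flat_performance, seed=10)
            if det_b.mode == "screen":
                assert det_a.mode == "screen"
                assert det_a.age <= det_b.age
            n_det_a += det_a.mode == "screen"
            n_det_b += det_b.mode == "screen"
            if t is None:
                # no detection truncation: screens and FPs are supersets
                fp_a = {e.age for e in det_a.events if e.result == "false_positive"}
                fp_b = {e.age for e in det_b.events if e.result == "false_positive"}
                assert fp_b <= fp_a
                assert len(det_a.events) >= len(det_b.events)
        assert n_det_a >= n_det_b > 0
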