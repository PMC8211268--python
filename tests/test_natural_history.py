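import copy
import math

import numpy as np
import pytest
from scipy import optimize, stats

from conftest import constant_incidence_params, make_woman
from mammosim.natural_history import (
    assign_stage,
    assign_subtype,
    build_tumor_history,
    gompertz_crossing_time,
    gompertz_diameter,
    make_stage_fn,
    progress_stage_dwell,
    sample_clinical_incidence,
    sample_sojourn,
    stage_at,
)
from mammosim.rng import substream


class TestClinicalIncidence:
    def test_zero_hazard_never_detects(self, default_params, rng, woman):
        p = constant_incidence_params(0.0, default_params)
        assert all(sample_clinical_incidence(woman, p, rng) is None for _ in range(100))

    def test_exponential_cumulative_incidence(self, default_params, rng, woman):
        p = constant_incidence_params(200.0, default_params)
        n = 100_000
        hits = sum(
            (a := sample_clinical_incidence(woman, p, rng)) is not None and a <= 80 for _ in range(n)
        )
        target = 1 - math.exp(-0.002 * 80)
        se = math.sqrt(target * (1 - target) / n)
        assert hits / n == pytest.approx(target, abs=3 * se)

    def test_risk_multiplier_closed_form(self, default_params, rng):
        p = constant_incidence_params(200.0, default_params)
        w = make_woman(risk_multiplier=0.25)
        n = 100_000
        hits = sum(
            (a := sample_clinical_incidence(w, p, rng)) is not None and a <= 80 for _ in range(n)
        )
        target = 1 - math.exp(-0.002 * 0.25 * 80)
        se = math.sqrt(target * (1 - target) / n)
        assert hits / n == pytest.approx(target, abs=3 * se)

    def test_not_truncated_at_other_cause_death(self, default_params, rng):
        p = constant_incidence_params(5000.0, default_params)
        w = make_woman(death_age=1.0)
        draws = [sample_clinical_incidence(w, p, rng) for _ in range(500)]
        assert any(a is not None and a > 1.0 for a in draws)

    def test_matches_day_grid_oracle(self, default_params):
        # high rate so nearly every draw yields an age: the conditioned
        # sample stays ~1e5 and the two-sample KS noise floor stays < 0.01
        p = constant_incidence_params(3000.0, default_params)
        w = make_woman()
        n = 100_000
        s = substream(11, "nh-ks")
        ages = np.array(
            [a for a in (sample_clinical_incidence(w, p, s) for _ in range(n)) if a is not None]
        )
        h = 0.03 / 365.0
        cum = np.arange(120 * 365 + 1) * h
        e = substream(12, "nh-ks-oracle").exponential(size=n)
        days = np.searchsorted(cum, e, side="right") - 1
        oracle = days[days < 120 * 365] / 365.0
        assert stats.ks_2samp(ages, oracle).statistic < 0.01


class TestSubtype:
    def test_degenerate(self, default_params, rng):
        p = copy.copy(default_params)
        probs = default_params.subtype_probs.copy()
        probs.loc[:] = [[1, 0, 0, 0], [1, 0, 0, 0]]
        p.subtype_probs = probs
        assert all(assign_subtype(45, p, rng) == "ER+/HER2-" for _ in range(100))

    def test_frequencies(self, default_params, rng):
        p = copy.copy(default_params)
        probs = default_params.subtype_probs.copy()
        probs.loc[:] = [[0.6, 0.1, 0.1, 0.2]] * 2
        p.subtype_probs = probs
        n = 100_000
        draws = [assign_subtype(45, p, rng) for _ in range(n)]
        for sub, target in zip(p.subtype_probs.columns, (0.6, 0.1, 0.1, 0.2)):
            se = math.sqrt(target * (1 - target) / n)
            assert draws.count(sub) / n == pytest.approx(target, abs=3 * se)

    def test_partition(self, default_params, rng):
        subs = set(default_params.subtype_probs.columns)
        for _ in range(200):
            assert assign_subtype(60, default_params, rng) in subs


class TestSojourn:
    def test_fixed_mode_exact(self, default_params, rng):
        p = copy.copy(default_params)
        p.sojourn_mode = "fixed"
        means = default_params.sojourn_means.copy()
        means.loc[:] = 2.0
        p.sojourn_means = means
        sojourn, onset = sample_sojourn("ER+/HER2-", 50.0, p, rng)
        assert sojourn == 2.0 and onset == 48.0

    def test_exponential_tail(self, default_params, rng):
        p = copy.copy(default_params)
        means = default_params.sojourn_means.copy()
        means.loc[:] = 2.0
        p.sojourn_means = means
        n = 100_000
        tail = sum(sample_sojourn("ER+/HER2-", 80.0, p, rng)[0] > 4.0 for _ in range(n)) / n
        target = math.exp(-2)
        se = math.sqrt(target * (1 - target) / n)
        assert tail == pytest.approx(target, abs=3 * se)

    def test_onset_subtraction(self, default_params, rng):
        p = copy.copy(default_params)
        p.sojourn_mode = "fixed"
        means = default_params.sojourn_means.copy()
        means.loc[:] = 3.0
        p.sojourn_means = means
        sojourn, onset = sample_sojourn("ER-/HER2-", 50.0, p, rng)
        assert onset == pytest.approx(47.0)

    def test_onset_floored_at_zero(self, default_params, rng):
        p = copy.copy(default_params)
        p.sojourn_mode = "fixed"
        means = default_params.sojourn_means.copy()
        means.loc[:] = 10.0
        p.sojourn_means = means
        sojourn, onset = sample_sojourn("ER+/HER2-", 4.0, p, rng)
        assert onset == 0.0 and sojourn == pytest.approx(4.0)

    def test_nonpositive_mean_rejected(self, default_params, rng):
        p = copy.copy(default_params)
        means = default_params.sojourn_means.copy()
        means.loc[:] = 0.0
        p.sojourn_means = means
        with pytest.raises(ValueError, match="positive"):
            sample_sojourn("ER+/HER2-", 50.0, p, rng)


class TestStageTable:
    def test_degenerate(self, default_params, rng):
        p = copy.copy(default_params)
        sd = default_params.stage_dists.copy()
        sd.loc[sd["mode"] == "screen", ["local", "regional", "distant"]] = [1.0, 0.0, 0.0]
        p.stage_dists = sd
        assert all(assign_stage("screen", 55, p, rng) == "local" for _ in range(100))

    def test_frequencies(self, default_params, rng):
        n = 100_000
        draws = [assign_stage("clinical", 55, default_params, rng) for _ in range(n)]
        row = default_params.stage_dists
        row = row[(row["mode"] == "clinical") & (row["age_group"] == "50-64")].iloc[0]
        for st in ("local", "regional", "distant"):
            target = row[st]
            se = math.sqrt(target * (1 - target) / n)
            assert draws.count(st) / n == pytest.approx(target, abs=3 * se)

    def test_screen_stages_earlier_in_fixture(self, default_params):
        sd = default_params.stage_dists
        for ag in sd["age_group"].unique():
            p_scr = sd[(sd["mode"] == "screen") & (sd["age_group"] == ag)].iloc[0]["local"]
            p_cli = sd[(sd["mode"] == "clinical") & (sd["age_group"] == ag)].iloc[0]["local"]
            assert p_scr > p_cli

    def test_missing_stratum(self, default_params, rng):
        with pytest.raises(KeyError, match="stage_dists"):
            assign_stage("mri", 55, default_params, rng)


class TestStageDwell:
    def test_infinite_dwell_stays_local(self, rng):
        entries = progress_stage_dwell(50.0, {"local": 1e12, "regional": 1e12}, rng)
        for t in (50.0, 80.0, 119.0):
            assert stage_at(t, entries) == "local"

    def test_exponential_still_local(self, rng):
        n = 100_000
        still = sum(
            stage_at(51.0, progress_stage_dwell(50.0, {"local": 2.0, "regional": 1.0}, rng)) == "local"
            for _ in range(n)
        )
        target = math.exp(-0.5)
        se = math.sqrt(target * (1 - target) / n)
        assert still / n == pytest.approx(target, abs=3 * se)

    def test_entries_strictly_increasing(self, rng):
        for _ in range(500):
            e = progress_stage_dwell(40.0, {"local": 2.0, "regional": 1.5}, rng)
            assert e["local"] < e["regional"] < e["distant"]

    def test_query_before_onset(self, rng):
        entries = progress_stage_dwell(50.0, {"local": 2.0, "regional": 1.0}, rng)
        with pytest.raises(ValueError, match="before onset"):
            stage_at(49.0, entries)


class TestGompertz:
    GP = {"d0_mm": 2.0, "dmax_mm": 128.0, "rate_per_year": 0.5, "lag_years": 1.0}

    def test_lag_boundary(self):
        assert gompertz_diameter(self.GP["lag_years"], self.GP) == pytest.approx(2.0)
        assert gompertz_diameter(0.0, self.GP) == pytest.approx(2.0)

    def test_asymptote(self):
        assert gompertz_diameter(500.0, self.GP) == pytest.approx(128.0, rel=1e-6)

    def test_monotone(self):
        ts = np.linspace(0, 30, 200)
        ds = [gompertz_diameter(t, self.GP) for t in ts]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_crossing_time_closed_form_vs_bisection(self):
        t = gompertz_crossing_time(self.GP, 20.0)
        expected = self.GP["lag_years"] + 2 * math.log(math.log(64) / math.log(6.4))
        assert t == pytest.approx(expected)
        root = optimize.brentq(lambda x: gompertz_diameter(x, self.GP) - 20.0, 1.0, 100.0)
        assert t == pytest.approx(root, abs=1e-9)

    def test_thresholds_outside_range(self):
        assert gompertz_crossing_time(self.GP, 1.0) == 0.0
        assert gompertz_crossing_time(self.GP, 200.0) == math.inf

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            gompertz_diameter(1.0, {**self.GP, "d0_mm": 200.0})


class TestBuildTumorHistory:
    def test_counterfactual_stability(self, default_params, woman):
        a = build_tumor_history(woman, default_params, seed=42)
        b = build_tumor_history(woman, default_params, seed=42)
        assert a == b

    def test_fields_consistent(self, default_params):
        found = 0
        for wid in range(400):
            w = make_woman(wid=wid)
            t = build_tumor_history(w, default_params, seed=13)
            if t is None:
                continue
            found += 1
            assert t.preclinical_onset_age < t.clinical_detection_age
            assert t.sojourn_years > 0
            assert t.stage_at_clinical in ("local", "regional", "distant")
        assert found > 0

    def test_dwell_mechanism_populates_entries(self, default_params):
        p = copy.copy(default_params)
        p.stage_mechanism = "dwell"
        for wid in range(200):
            t = build_tumor_history(make_woman(wid=wid), p, seed=13)
            if t is not None:
                assert t.dwell_entry_ages is not None
                ages = t.dwell_entry_ages
                assert ages["local"] < ages["regional"] < ages["distant"]
                return
        pytest.fail("no tumors generated")

    def test_growth_mechanism_stage_earlier_when_detected_earlier(self, default_params):
        p = copy.copy(default_params)
        p.stage_mechanism = "growth"
        for wid in range(300):
            w = make_woman(wid=wid)
            t = build_tumor_history(w, p, seed=29)
            if t is None:
                continue
            fn = make_stage_fn(w, t, p, seed=29)
            order = {"local": 0, "regional": 1, "distant": 2}
            early = fn("screen", t.preclinical_onset_age + 0.01)
            late = fn("clinical", t.clinical_detection_age)
            assert order[early] <= order[late]
            return
        pytest.fail("no tumors generated")

    def test_dwell_earlier_detection_earlier_stage_in_expectation(self, default_params):
        # monotone stage shift when detection moves earlier (dwell variant)
        p = copy.copy(default_params)
        p.stage_mechanism = "dwell"
        order = {"local": 0, "regional": 1, "distant": 2}
        early_scores, late_scores = [], []
        for wid in range(3000):
            w = make_woman(wid=wid)
            t = build_tumor_history(w, p, seed=31)
            if t is None or t.sojourn_years < 1.0:
                continue
            fn = make_stage_fn(w, t, p, seed=31)
            early_scores.append(order[fn("screen", t.clinical_detection_age - 1.0)])
            late_scores.append(order[fn("clinical", t.clinical_detection_age)])
        assert np.mean(early_scores) < np.mean(late_scores)
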