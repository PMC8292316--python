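"""Pre/post-transition analyses: t-tests, profiles, midpoint test, SJL."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronodst import analysis as an
from chronodst.config import CohortConfig, RunConfig
from chronodst.events import classify_events, filter_min_duration, pair_same_weekday
from chronodst.pgs import score_cohort
from chronodst.synthetic import generate_cohort

DST = date(2019, 3, 10)


def _classified(cohort):
    return pair_same_weekday(filter_min_duration(
        classify_events(cohort.events, DST)))


@pytest.fixture(scope="module")
def pipeline(default_cohort):
    classified = _classified(default_cohort)
    result, _ = score_cohort(default_cohort.genotypes)
    return classified, result.group_map()


class TestTTests:
    def test_hand_welch_example(self):
        # {400, 410, 420} vs {390, 400, 410}: equal variances 100,
        # t = 10 / sqrt(100/3 + 100/3) = 1.2247
        t, _ = an._ttest(np.array([400.0, 410.0, 420.0]),
                         np.array([390.0, 400.0, 410.0]), "welch")
        assert t == pytest.approx(np.sqrt(1.5), abs=1e-9)
        assert t == pytest.approx(1.2247, abs=1e-4)

    def test_identical_samples_null(self):
        x = np.array([400.0, 410.0, 420.0])
        t, p = an._ttest(x, x.copy(), "welch")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_summary_reconstruction_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 80), rng.normal(0.3, 1.4, 60)
        t_direct, p_direct = an._ttest(x, y, "welch")
        t_sum, p_sum = an.welch_t_from_summary(
            x.mean(), x.std(ddof=1) / np.sqrt(x.size), x.size,
            y.mean(), y.std(ddof=1) / np.sqrt(y.size), y.size)
        assert t_sum == pytest.approx(t_direct, abs=1e-10)
        assert p_sum == pytest.approx(p_direct, abs=1e-10)

    def test_student_flavour_pools_variance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0, 3, 8)
        t_student, _ = an._ttest(x, y, "student")
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t_student == pytest.approx(float(ref.statistic), abs=1e-12)


class TestAsleepTime:
    def test_null_cohort_gives_null_t(self):
        # no DST response, no weekend effect: before/after asleep time differs
        # only by sampling noise around a common distribution
        cfg = CohortConfig(n_subjects=120, seed=17, adjust_days_morning=0,
                           persistent_delay_evening=0.0, free_night_delay=0.0,
                           work_night_floor_fraction=1.0)
        cohort = generate_cohort(cfg)
        classified = _classified(cohort)
        result, _ = score_cohort(cohort.genotypes)
        out = an.asleep_time_comparison(classified, result.group_map())
        for r in out.values():
            assert abs(r.statistic) < 3.0
            assert r.p_value > 0.001

    def test_reports_cell_sizes(self, pipeline):
        classified, groups = pipeline
        out = an.asleep_time_comparison(classified, groups)
        for r in out.values():
            for w in ("before", "after"):
                assert r.group_stats[w]["n"] > 50
                assert r.group_stats[w]["sem"] > 0


class TestProfiles:
    def test_noise_free_recovery_exact(self, noise_free_cohort):
        classified = _classified(noise_free_cohort)
        profiles = an.daily_profiles(classified, noise_free_cohort.true_group_map())
        shifts = an.profile_shifts(profiles)
        ev = shifts[shifts["group"] == "evening"].set_index("weekday")
        assert ev.loc["Friday", "shift_onset_min"] == pytest.approx(45.0, abs=0.51)
        assert ev.loc["Sunday", "shift_onset_min"] == pytest.approx(60.0, abs=0.51)
        mo = shifts[shifts["group"] == "morning"].set_index("weekday")
        for wd in ("Tuesday", "Wednesday", "Thursday", "Friday", "Saturday"):
            assert mo.loc[wd, "shift_onset_min"] == pytest.approx(0.0, abs=0.51)

    def test_single_event_cell_equals_event_times(self):
        rows = []
        for night in (date(2019, 3, 4), date(2019, 3, 11)):  # paired Mondays
            start = datetime(night.year, night.month, night.day, 22, 30)
            rows.append({"subject_id": "a", "start": start,
                         "end": start + timedelta(minutes=435),
                         "minutes_asleep": 420, "minutes_in_bed": 435})
        classified = pair_same_weekday(filter_min_duration(
            classify_events(pd.DataFrame(rows), DST)))
        profiles = an.daily_profiles(classified, {"a": "morning"})
        cell = profiles[(profiles["group"] == "morning")
                        & (profiles["window"] == "before")
                        & (profiles["weekday"] == "Monday")].iloc[0]
        assert cell["mean_onset"] == pytest.approx(22.5, abs=1e-9)
        assert cell["n"] == 1
        empty = profiles[(profiles["group"] == "evening")]
        assert (empty["n"] == 0).all()

    def test_midnight_straddle_uses_circular_mean(self):
        # {23:30, 00:30} must average to midnight, not noon
        rows = []
        for day, hh, mm in ((4, 23, 30), (6, 0, 30), (11, 23, 30), (13, 0, 30)):
            start = datetime(2019, 3, day, hh, mm)
            rows.append({"subject_id": "a", "start": start,
                         "end": start + timedelta(minutes=435),
                         "minutes_asleep": 420, "minutes_in_bed": 435})
        classified = pair_same_weekday(filter_min_duration(
            classify_events(pd.DataFrame(rows), DST)))
        profiles = an.daily_profiles(classified, {"a": "morning"})
        cells = profiles[profiles["n"] > 0]
        onsets = cells["mean_onset"].to_numpy()
        assert np.all((onsets >= 23.0) | (onsets <= 1.0))


class TestMidpointDistribution:
    def test_morning_earlier_than_evening(self, pipeline, default_cohort):
        classified, groups = pipeline
        for night_class in ("work", "free"):
            res = an.midpoint_distribution_test(classified, groups,
                                                night_class, DST)
            assert res.statistic_kind == "F"
            assert res.group_stats["morning"]["mean"] < \
                res.group_stats["evening"]["mean"]
            assert res.p_value < 0.05

    def test_identical_groups_give_zero_f(self):
        rows = []
        for sid in ("a", "b"):
            for day, minute in ((3, 0), (4, 30), (5, 45)):
                start = datetime(2019, 3, day, 23, minute)
                rows.append({"subject_id": sid, "start": start,
                             "end": start + timedelta(minutes=435),
                             "minutes_asleep": 420, "minutes_in_bed": 435})
        classified = pair_same_weekday(filter_min_duration(
            classify_events(pd.DataFrame(rows), DST)))
        res = an.midpoint_distribution_test(
            classified, {"a": "morning", "b": "evening"}, "work", DST)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_power_at_study_scale(self):
        # groups separated by 11 min at sleep-like concentration and
        # study-scale n reject the equal-means null almost always
        rng = np.random.default_rng(99)
        from chronodst import circular as c
        n, kappa = 2700, 8.0
        rejections = 0
        for _ in range(10):
            g1 = rng.vonmises(c.hours_to_angle(3.25), kappa, size=n)
            g2 = rng.vonmises(c.hours_to_angle(3.25 + 11 / 60), kappa, size=n)
            if c.watson_williams([g1, g2]).p_value < 0.05:
                rejections += 1
        assert rejections >= 9


class TestSocialJetlag:
    @staticmethod
    def _table(rows):
        out = []
        for sid, day, hh, mm, asleep in rows:
            start = datetime(2019, 3, day, hh, mm)
            out.append({"subject_id": sid, "start": start,
                        "end": start + timedelta(minutes=asleep + 15),
                        "minutes_asleep": asleep, "minutes_in_bed": asleep + 15})
        return pair_same_weekday(filter_min_duration(
            classify_events(pd.DataFrame(out), DST)))

    def test_constant_shift(self):
        # work midpoints 02:00 x4, free 03:00 x2 -> sjl = +60
        rows = [("a", d, 22, 0, 480) for d in (4, 5, 6, 7)]       # Mon-Thu
        rows += [("a", d, 23, 0, 480) for d in (8, 9)]            # Fri, Sat
        table, _, _ = _sjl_no_groups(self._table(rows))
        assert table.iloc[0]["sjl_minutes"] == pytest.approx(60.0, abs=1e-6)

    def test_circular_work_mean(self):
        # work midpoints {01:30, 02:30} -> 02:00; free {03:00} -> +60
        rows = [("a", 4, 21, 30, 480), ("a", 5, 22, 30, 480),
                ("a", 8, 23, 0, 480)]
        table, _, _ = _sjl_no_groups(self._table(rows))
        assert table.iloc[0]["sjl_minutes"] == pytest.approx(60.0, abs=1e-6)

    def test_identical_midpoints_zero(self):
        rows = [("a", 4, 22, 0, 480), ("a", 8, 22, 0, 480)]
        table, _, _ = _sjl_no_groups(self._table(rows))
        assert table.iloc[0]["sjl_minutes"] == pytest.approx(0.0, abs=1e-9)

    def test_one_sided_subjects_excluded(self):
        rows = [("a", 4, 22, 0, 480),   # work only
                ("b", 8, 22, 0, 480)]   # free only
        table, _, n_excluded = _sjl_no_groups(self._table(rows))
        assert len(table) == 0
        assert n_excluded == 2

    def test_evening_sjl_increases_after_transition(self, pipeline):
        classified, groups = pipeline
        _, comparisons, _ = an.social_jetlag(classified, groups)
        ev = comparisons["evening"].group_stats
        mo = comparisons["morning"].group_stats
        ev_change = ev["after"]["mean"] - ev["before"]["mean"]
        mo_change = mo["after"]["mean"] - mo["before"]["mean"]
        assert ev_change > 0
        assert ev_change > abs(mo_change)


def _sjl_no_groups(classified):
    """Per-subject SJL table only (tiny fixtures cannot support t-tests)."""
    table, n_excluded = an.compute_sjl_table(classified)
    return table, None, n_excluded


class TestFullAnalysis:
    def test_bundle_and_determinism(self, default_cohort):
        cfg = RunConfig(dst_date=DST, seed=11)
        a = an.run_full_analysis(default_cohort.events,
                                 default_cohort.genotypes, cfg)
        b = an.run_full_analysis(default_cohort.events,
                                 default_cohort.genotypes, cfg)
        assert a.counts.equals(b.counts)
        assert a.profiles.equals(b.profiles)
        assert a.sjl_table.equals(b.sjl_table)
        import json
        assert json.dumps(a.comparisons, sort_keys=True, default=float) == \
            json.dumps(b.comparisons, sort_keys=True, default=float)
        assert set(a.comparisons) == {"asleep_time", "midpoint_distribution",
                                      "social_jetlag"}

    def test_global_null(self):
        cfg = CohortConfig(n_subjects=150, seed=23, adjust_days_morning=0,
                           persistent_delay_evening=0.0,
                           work_night_floor_fraction=1.0,
                           genetic_signal_fraction=0.0)
        cohort = generate_cohort(cfg)
        bundle = an.run_full_analysis(cohort.events, cohort.genotypes,
                                      RunConfig(dst_date=DST))
        for r in bundle.comparisons["asleep_time"].values():
            assert r["p_value"] > 0.001
        for r in bundle.comparisons["social_jetlag"].values():
            assert r["p_value"] > 0.001
        shifts = bundle.shifts
        assert shifts["shift_onset_min"].abs().max() < 15.0
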