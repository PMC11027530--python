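"""Weekly profiles, annual series, and the two SIDS correlation screens."""

import numpy as np
import pandas as pd
import pytest

from oracles import pearson_direct
from sidscreen.etl import add_derived_columns
from sidscreen.profiles import (
    AnnualSeries,
    ProfileCorrelationScreen,
    ScreenSets,
    TrendCorrelationScreen,
    WeeklyProfile,
    annual_series,
    intersect_screens,
    profile_screen,
    trend_screen,
    weekly_profile,
)
from sidscreen.synthetic import CauseSpec, CohortConfig, generate_cohort


def _profile_from_counts(jid, week_counts: dict[int, int]) -> WeeklyProfile:
    counts = np.zeros(53, dtype=int)
    for wk, n in week_counts.items():
        counts[wk] = n
    return WeeklyProfile(joined_id=jid, counts=counts)


def _records_at_weeks(weeks):
    return pd.DataFrame(
        {"age_at_death_weeks": weeks, "year": [2000] * len(weeks)}
    )


class TestWeeklyProfile:
    def test_counts_and_frequencies(self):
        p = weekly_profile(_records_at_weeks([1, 1, 2]), "x")
        assert p.counts[1] == 2 and p.counts[2] == 1
        assert p.frequencies[1] == pytest.approx(2 / 3)
        assert p.frequencies[2] == pytest.approx(1 / 3)
        assert p.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_single_week(self):
        p = weekly_profile(_records_at_weeks([11] * 10), "x")
        assert p.frequencies[11] == 1.0
        assert p.counts.sum() == 10

    def test_zero_records_is_an_error(self):
        with pytest.raises(ValueError):
            weekly_profile(_records_at_weeks([]), "x")

    def test_synthetic_sids_like_cause_peaks_near_week_11(self):
        cfg = CohortConfig(
            causes=[CauseSpec(name="s", icd9_codes=["798.0"], icd10_codes=["R95"],
                              annual_counts={2000: 5000},
                              profile_peak_week=11, profile_spread=4)],
            years=[2000], seed=3,
        )
        records = add_derived_columns(generate_cohort(cfg))
        p = weekly_profile(records, "s")
        assert 9 <= int(np.argmax(p.frequencies)) <= 13


class TestAnnualSeries:
    def test_percent_of_mean(self):
        rows = [{"joined_id": "a", "year": y} for y, n in
                [(2000, 50), (2001, 100), (2002, 150)] for _ in range(n)]
        s = annual_series(pd.DataFrame(rows), [2000, 2001, 2002], "a")
        assert list(s.normalized) == [50.0, 100.0, 150.0]
        assert s.normalized.mean() == pytest.approx(100.0, abs=1e-9)

    def test_constant_counts_normalize_to_100(self):
        rows = [{"joined_id": "a", "year": y} for y in [2000] * 30 + [2001] * 30]
        s = annual_series(pd.DataFrame(rows), [2000, 2001], "a")
        assert list(s.normalized) == [100.0, 100.0]

    def test_gap_years_are_excluded_from_the_mean(self):
        # deaths in 1991 and 1995; 1992-1994 out of scope entirely
        rows = (
            [{"joined_id": "a", "year": 1991} for _ in range(30)]
            + [{"joined_id": "a", "year": 1993} for _ in range(999)]
            + [{"joined_id": "a", "year": 1995} for _ in range(10)]
        )
        s = annual_series(pd.DataFrame(rows), [1991, 1995], "a")
        # hand recomputation: mean over {30, 10} = 20 -> 150%, 50%
        assert list(s.years) == [1991, 1995]
        assert list(s.normalized) == [150.0, 50.0]

    def test_all_zero_counts_is_an_error(self):
        rows = [{"joined_id": "a", "year": 1980}]
        with pytest.raises(ValueError):
            annual_series(pd.DataFrame(rows), [2000, 2001], "a")


class TestProfileScreen:
    def test_reference_self_correlation_is_exactly_one(self):
        profiles = {
            "ref": _profile_from_counts("ref", {10: 5, 11: 8, 12: 5}),
            "other": _profile_from_counts("other", {40: 10}),
        }
        screen = ProfileCorrelationScreen(reference_id="ref").fit(profiles)
        r_ref = screen.results_.set_index("joined_id").loc["ref", "r"]
        assert r_ref == 1.0
        assert "ref" in screen.selected_

    def test_r_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        profiles = {
            jid: _profile_from_counts(jid, {w: int(c) for w, c in
                                            enumerate(rng.integers(1, 50, 53))})
            for jid in ("ref", "a", "b")
        }
        screen = ProfileCorrelationScreen(reference_id="ref").fit(profiles)
        ref = profiles["ref"].frequencies
        for jid in ("a", "b"):
            expected, _ = pearson_direct(list(profiles[jid].frequencies), list(ref))
            got = screen.results_.set_index("joined_id").loc[jid, "r"]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_threshold_is_inclusive_at_the_boundary(self):
        profiles = {
            "ref": _profile_from_counts("ref", {0: 2, 2: 1}),
            "edge": _profile_from_counts("edge", {0: 2, 1: 1}),
        }
        r, _ = pearson_direct(
            list(profiles["edge"].frequencies), list(profiles["ref"].frequencies)
        )
        screen = ProfileCorrelationScreen(reference_id="ref", threshold=r).fit(profiles)
        assert "edge" in screen.selected_

    def test_constant_profiles_excluded_not_flagged(self):
        profiles = {
            "ref": _profile_from_counts("ref", {10: 5, 11: 8}),
            "flat": _profile_from_counts("flat", {w: 1 for w in range(53)}),
        }
        screen = ProfileCorrelationScreen(reference_id="ref").fit(profiles)
        assert screen.excluded_ == ["flat"]
        assert "flat" not in screen.selected_

    def test_missing_reference_is_an_error(self):
        with pytest.raises(KeyError):
            ProfileCorrelationScreen(reference_id="nope").fit(
                {"a": _profile_from_counts("a", {1: 1, 2: 3})}
            )

    def test_raising_threshold_never_grows_the_set(self):
        rng = np.random.default_rng(11)
        profiles = {
            jid: _profile_from_counts(jid, {w: int(c) for w, c in
                                            enumerate(rng.integers(0, 30, 53))})
            for jid in "refabcdefg"
        }
        profiles["ref"] = _profile_from_counts("ref", {10: 3, 11: 5, 12: 3})
        previous = None
        for thr in (0.0, 0.25, 0.5, 0.75, 0.9):
            sel = profile_screen(profiles, "ref", threshold=thr)
            if previous is not None:
                assert sel <= previous
            previous = sel


def _series(jid, years, counts):
    return AnnualSeries(jid, np.array(years), np.array(counts, dtype=float))


class TestTrendScreen:
    years = list(range(1996, 2006))

    def test_identical_series_included(self):
        ref = _series("ref", self.years, np.linspace(200, 100, 10))
        twin = _series("twin", self.years, np.linspace(100, 50, 10))
        screen = TrendCorrelationScreen(reference_id="ref").fit(
            {"ref": ref, "twin": twin}
        )
        row = screen.results_.set_index("joined_id").loc["twin"]
        assert row["r"] == pytest.approx(1.0)
        assert "twin" in screen.selected_

    def test_constant_series_excluded_and_logged(self):
        ref = _series("ref", self.years, np.linspace(200, 100, 10))
        flat = _series("flat", self.years, [30.0] * 10)
        screen = TrendCorrelationScreen(reference_id="ref").fit(
            {"ref": ref, "flat": flat}
        )
        assert screen.excluded_ == ["flat"]
        assert "flat" not in screen.selected_

    def test_r_and_p_match_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        ref_counts = np.linspace(300, 100, 10)
        noisy = ref_counts * 0.5 + rng.normal(0, 5, 10)
        flat = 50 + rng.normal(0, 1, 10)
        screens = TrendCorrelationScreen(reference_id="ref").fit(
            {
                "ref": _series("ref", self.years, ref_counts),
                "decline": _series("decline", self.years, noisy),
                "flat": _series("flat", self.years, flat),
            }
        )
        tbl = screens.results_.set_index("joined_id")
        ref_norm = 100 * ref_counts / ref_counts.mean()
        for jid, counts in (("decline", noisy), ("flat", flat)):
            norm = 100 * counts / counts.mean()
            r, p = pearson_direct(list(norm), list(ref_norm))
            assert tbl.loc[jid, "r"] == pytest.approx(r, rel=1e-10)
            assert tbl.loc[jid, "p"] == pytest.approx(p, rel=1e-8)
        assert "decline" in screens.selected_
        assert "flat" not in screens.selected_

    def test_fewer_than_three_years_is_an_error(self):
        ref = _series("ref", [2000, 2001], [10, 20])
        with pytest.raises(ValueError, match="3"):
            TrendCorrelationScreen(reference_id="ref").fit({"ref": ref})

    def test_mismatched_year_axes_rejected(self):
        ref = _series("ref", self.years, np.linspace(200, 100, 10))
        other = _series("o", [y + 1 for y in self.years], np.linspace(200, 100, 10))
        with pytest.raises(ValueError, match="axis"):
            TrendCorrelationScreen(reference_id="ref").fit({"ref": ref, "o": other})

    def test_lowering_alpha_never_grows_the_set(self):
        rng = np.random.default_rng(13)
        ref_counts = np.linspace(300, 100, 10)
        series = {"ref": _series("ref", self.years, ref_counts)}
        for i in range(8):
            series[f"c{i}"] = _series(
                f"c{i}", self.years, ref_counts + rng.normal(0, 40, 10)
            )
        previous = None
        for alpha in (0.5, 0.1, 0.01, 0.005, 0.0001):
            sel = trend_screen(series, "ref", alpha=alpha)
            if previous is not None:
                assert sel <= previous
            previous = sel


class TestIntersection:
    def test_plain_set_intersection(self):
        sets = ScreenSets("ref", {"A", "B", "C"}, {"B", "C", "D"})
        assert intersect_screens(sets) == {"B", "C"}

    def test_disjoint_sets_intersect_empty(self):
        sets = ScreenSets("ref", {"A"}, {"B"})
        assert intersect_screens(sets) == set()

    def test_without_reference_view(self):
        sets = ScreenSets("ref", {"ref", "A"}, {"ref", "A", "B"})
        assert sets.without_reference(sets.intersection) == {"A"}
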