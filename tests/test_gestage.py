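"""Gestational-age regression screen: summaries, OLS, subsets, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import ols_direct
from sidscreen.etl import add_derived_columns
from sidscreen.gestage import (
    GestationalAgeScreen,
    fit_gestage_regression,
    per_gestweek_summary,
    run_screen,
)
from sidscreen.synthetic import CauseSpec, CohortConfig, generate_cohort


def _frame(pairs, **extra):
    df = pd.DataFrame(
        {
            "gestational_age_weeks": [g for g, _ in pairs],
            "age_at_death_weeks": [w for _, w in pairs],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestPerGestweekSummary:
    def test_hand_arithmetic(self):
        tbl = per_gestweek_summary(_frame([(40, 10), (40, 14)]))
        row = tbl.set_index("gestational_age_weeks").loc[40]
        assert row["n"] == 2
        assert row["mean_age_weeks"] == pytest.approx(12.0)
        assert row["sd_age_weeks"] == pytest.approx(np.sqrt(8), abs=1e-12)

    def test_single_record_has_no_sd(self):
        tbl = per_gestweek_summary(_frame([(28, 5)]))
        row = tbl.set_index("gestational_age_weeks").loc[28]
        assert row["n"] == 1 and row["mean_age_weeks"] == 5.0
        assert np.isnan(row["sd_age_weeks"])

    def test_planted_negative_slope_shows_in_weekly_means(self):
        cfg = CohortConfig(
            causes=[CauseSpec(name="s", icd9_codes=["798.0"], icd10_codes=["R95"],
                              annual_counts={2000: 4000}, profile_peak_week=20,
                              profile_spread=0.1, gestage_slope=-0.6,
                              gestage_noise_sd=8)],
            years=[2000], seed=2,
        )
        records = add_derived_columns(generate_cohort(cfg))
        tbl = per_gestweek_summary(records)
        window = tbl[tbl["gestational_age_weeks"].between(25, 40)]
        rho, _ = stats.spearmanr(window["gestational_age_weeks"],
                                 window["mean_age_weeks"])
        assert rho < -0.5


class TestFitGestageRegression:
    def test_exact_line_recovered(self):
        pairs = [(g, 60 - 1.5 * g) for g in (30, 34, 38, 42)]
        res = fit_gestage_regression(_frame(pairs))
        assert res.slope == pytest.approx(-1.5, abs=1e-10)
        assert res.intercept == pytest.approx(60.0, abs=1e-8)
        assert res.p_value < 1e-10
        assert res.passes

    def test_zero_slope_never_passes(self):
        # y identical at both design points: slope exactly 0
        pairs = [(30, 5), (30, 9), (40, 5), (40, 9)]
        res = fit_gestage_regression(_frame(pairs))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert not res.passes

    def test_positive_slope_never_passes_even_if_significant(self):
        pairs = [(g, 1.5 * g) for g in (30, 34, 38, 42)]
        res = fit_gestage_regression(_frame(pairs))
        assert res.p_value < 1e-10 and not res.passes

    def test_agrees_with_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            g = rng.integers(20, 45, n).astype(float)
            w = 30 - 0.4 * g + rng.normal(0, 5, n)
            res = fit_gestage_regression(_frame(list(zip(g, w))))
            slope, intercept, p = ols_direct(list(g), list(w))
            assert res.slope == pytest.approx(slope, rel=1e-10)
            assert res.intercept == pytest.approx(intercept, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_planted_slope_recovered(self):
        cfg = CohortConfig(
            causes=[CauseSpec(name="s", icd9_codes=["798.0"], icd10_codes=["R95"],
                              annual_counts={2000: 2000}, profile_peak_week=20,
                              profile_spread=0.1, gestage_slope=-0.6,
                              gestage_noise_sd=8)],
            years=[2000], seed=1,
        )
        records = add_derived_columns(generate_cohort(cfg))
        res = fit_gestage_regression(records)
        assert res.slope == pytest.approx(-0.6, abs=0.15)
        assert res.passes

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError, match="records"):
            fit_gestage_regression(_frame([(30, 5), (40, 9)]))

    def test_single_gestational_week_is_an_error(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_gestage_regression(_frame([(30, 5), (30, 9), (30, 7)]))

    def test_weighted_by_week_variant_matches_on_balanced_design(self):
        # one record per gestational week: means == records, weights equal
        pairs = [(g, 60 - 1.5 * g) for g in range(30, 44)]
        rec = fit_gestage_regression(_frame(pairs))
        wls = fit_gestage_regression(_frame(pairs), weight_by_week=True)
        assert wls.slope == pytest.approx(rec.slope, rel=1e-10)


class TestRunScreen:
    def _harmonized(self):
        causes = [
            CauseSpec(name="neg", icd9_codes=["777.5"], icd10_codes=["P77"],
                      annual_counts={y: 400 for y in (1990, 1997, 2002)},
                      profile_peak_week=25, profile_spread=2,
                      gestage_slope=-0.6, gestage_noise_sd=4),
            CauseSpec(name="pos", icd9_codes=["427.5"], icd10_codes=["I469"],
                      annual_counts={y: 400 for y in (1990, 1997, 2002)},
                      profile_peak_week=25, profile_spread=2,
                      gestage_slope=0.5, gestage_noise_sd=4),
        ]
        cfg = CohortConfig(causes=causes, years=[1990, 1997, 2002], seed=6)
        records = add_derived_columns(generate_cohort(cfg))
        records["joined_id"] = records["cause_code"].map(
            {"7775": "neg", "P77": "neg", "4275": "pos", "I469": "pos"}
        )
        return records

    def test_planted_negative_cause_passes_in_every_era(self):
        screen = GestationalAgeScreen(
            subsets=("all", "before", "during", "after")
        ).fit(self._harmonized())
        for label in ("all", "before", "during", "after"):
            assert screen.passed_[label] == {"neg"}

    def test_cause_absent_from_a_subset_reported_unfit(self):
        records = self._harmonized()
        icd10_only = records[records["icd_version"] == 10]
        tbl = run_screen(icd10_only, subsets=("icd9", "icd10"))
        icd9_rows = tbl[tbl["subset"] == "icd9"]
        assert set(icd9_rows["joined_id"]) == {"neg", "pos"}
        assert not icd9_rows["fit_ok"].any()
        icd10_rows = tbl[tbl["subset"] == "icd10"]
        assert icd10_rows["fit_ok"].all()

    def test_unknown_subset_label_is_an_error(self):
        with pytest.raises(ValueError, match="subset"):
            run_screen(self._harmonized(), subsets=("all", "weekend"))

    def test_passes_flag_matches_criterion_conjunction(self):
        tbl = run_screen(self._harmonized(), subsets=("all",))
        fit = tbl[tbl["fit_ok"]]
        expected = (fit["slope"] < 0) & (fit["p_value"] < 0.05)
        assert (fit["passes"] == expected).all()

    def test_sklearn_params_roundtrip(self):
        est = GestationalAgeScreen(alpha=0.01, subsets=("all",))
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05
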