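"""Gestational-age vs age-at-death regression screen.

The screen asks, for each harmonized cause group: do infants born earlier die
*later*?  Age at death (weeks, record level) is regressed on gestational age
at birth (weeks) by ordinary least squares, and a cause passes when the slope
is negative and its two-sided t-test p-value (n−2 df) is below 0.05.  A
negative slope is the signature of a critical developmental period anchored to
conceptional rather than postnatal age: a preterm infant reaches the dangerous
developmental window at a later postnatal age.

The regression is fit on record-level points, not on the per-gestational-week
means used for display; the per-week summary (n, mean, SD) is produced
separately as the plotting table.  A means-weighted variant
(``weight_by_week=True``) regresses weekly means weighted by week counts — a
sensitivity check that reproduces the display-level fit.

The screen is repeated on subsets — "Back to Sleep" eras (before/during/after)
and single ICD revisions — to rule out diagnostic-drift artifacts.  Causes
with too few records to identify a slope (fewer than 3 records or a single
distinct gestational week) are reported as unfit rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "GestAgeScreenResult",
    "per_gestweek_summary",
    "fit_gestage_regression",
    "run_screen",
    "GestationalAgeScreen",
    "SUBSET_LABELS",
]

SUBSET_LABELS = ("all", "before", "during", "after", "icd9", "icd10")

MIN_RECORDS = 3
MIN_DISTINCT_WEEKS = 2


@dataclass
class GestAgeScreenResult:
    """Per-cause, per-subset regression outcome.

    ``passes`` is True iff ``slope < 0 and p_value < alpha`` (the screening
    criterion); ``fit_ok`` is False when the subset had too few records or no
    gestational-age variation, in which case the estimates are NaN.
    """

    joined_id: str
    subset: str
    slope: float
    intercept: float
    p_value: float
    n: int
    passes: bool
    fit_ok: bool = True


def per_gestweek_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gestational-week n, mean and SD of age at death (weeks).

    Sample SD (n−1 denominator), reported only for weeks with n >= 2.  This is
    the table behind the mean±SD display of the gestational-age relationship.
    """
    if records.empty:
        raise ValueError("cannot summarize zero records")
    grouped = records.groupby("gestational_age_weeks")["age_at_death_weeks"]
    out = grouped.agg(n="size", mean_age_weeks="mean", sd_age_weeks="std")
    return out.reset_index()


def fit_gestage_regression(
    records: pd.DataFrame,
    joined_id: str = "",
    subset: str = "all",
    alpha: float = 0.05,
    weight_by_week: bool = False,
) -> GestAgeScreenResult:
    """OLS of age at death (weeks) on gestational age (weeks) for one cause.

    Record-level fit; two-sided slope p-value from the t distribution with
    n−2 degrees of freedom.  Raises ``ValueError`` below the minimum fit size
    (3 records spanning at least 2 distinct gestational weeks) — use
    :func:`run_screen` to get an "unfit" result object instead.
    """
    g = records["gestational_age_weeks"].to_numpy(dtype=float)
    w = records["age_at_death_weeks"].to_numpy(dtype=float)
    n = len(records)
    if n < MIN_RECORDS:
        raise ValueError(
            f"cause {joined_id!r} subset {subset!r}: {n} records < {MIN_RECORDS}"
        )
    if len(np.unique(g)) < MIN_DISTINCT_WEEKS:
        raise ValueError(
            f"cause {joined_id!r} subset {subset!r}: slope unidentifiable "
            "(all records at one gestational week)"
        )
    if weight_by_week:
        tbl = per_gestweek_summary(records)
        model = sm.WLS(
            tbl["mean_age_weeks"].to_numpy(),
            sm.add_constant(tbl["gestational_age_weeks"].to_numpy(dtype=float)),
            weights=tbl["n"].to_numpy(dtype=float),
        )
    else:
        model = sm.OLS(w, sm.add_constant(g))
    fit = model.fit()
    slope = float(fit.params[1])
    p_value = float(fit.pvalues[1])
    return GestAgeScreenResult(
        joined_id=joined_id,
        subset=subset,
        slope=slope,
        intercept=float(fit.params[0]),
        p_value=p_value,
        n=n,
        passes=(slope < 0) and (p_value < alpha),
    )


def _subset_mask(records: pd.DataFrame, subset: str) -> pd.Series:
    if subset == "all":
        return pd.Series(True, index=records.index)
    if subset in ("before", "during", "after"):
        return records["era"] == subset
    if subset == "icd9":
        return records["icd_version"] == 9
    if subset == "icd10":
        return records["icd_version"] == 10
    raise ValueError(f"unknown subset label {subset!r}")


class GestationalAgeScreen(BaseEstimator):
    """Run the slope<0 & p<alpha screen over causes and data subsets.

    Parameters
    ----------
    alpha:
        Significance level for the two-sided slope test.  Default 0.05.
    subsets:
        Subset labels to evaluate; any of ``all, before, during, after,
        icd9, icd10``.
    weight_by_week:
        Fit on per-gestational-week means (weighted) instead of record level.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (cause, subset): slope, intercept, p_value, n, passes,
        fit_ok.  Unfit (cause, subset) pairs appear with ``fit_ok=False``.
    passed_ : dict[str, set[str]]
        For each subset, the causes that pass the criterion.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        subsets: Sequence[str] = ("all",),
        weight_by_week: bool = False,
    ):
        self.alpha = alpha
        self.subsets = subsets
        self.weight_by_week = weight_by_week

    def fit(self, X: pd.DataFrame, y=None):
        for label in self.subsets:
            if label not in SUBSET_LABELS:
                raise ValueError(f"unknown subset label {label!r}")
        all_causes = sorted(X["joined_id"].unique())
        rows: list[GestAgeScreenResult] = []
        for label in self.subsets:
            sub = X[_subset_mask(X, label)]
            present = set(sub["joined_id"])
            # a cause with no records in a subset is still reported, as unfit
            for jid in all_causes:
                if jid not in present:
                    rows.append(
                        GestAgeScreenResult(
                            joined_id=jid,
                            subset=label,
                            slope=float("nan"),
                            intercept=float("nan"),
                            p_value=float("nan"),
                            n=0,
                            passes=False,
                            fit_ok=False,
                        )
                    )
            for jid, group in sub.groupby("joined_id", sort=True):
                try:
                    rows.append(
                        fit_gestage_regression(
                            group,
                            joined_id=jid,
                            subset=label,
                            alpha=self.alpha,
                            weight_by_week=self.weight_by_week,
                        )
                    )
                except ValueError:
                    rows.append(
                        GestAgeScreenResult(
                            joined_id=jid,
                            subset=label,
                            slope=float("nan"),
                            intercept=float("nan"),
                            p_value=float("nan"),
                            n=len(group),
                            passes=False,
                            fit_ok=False,
                        )
                    )
        df = pd.DataFrame([vars(r) for r in rows])
        df["subset"] = pd.Categorical(df["subset"], categories=list(self.subsets))
        df = df.sort_values(["subset", "joined_id"], ignore_index=True)
        df["subset"] = df["subset"].astype(str)
        self.results_ = df
        self.passed_ = {
            label: set(
                self.results_.loc[
                    (self.results_["subset"] == label) & self.results_["passes"],
                    "joined_id",
                ]
            )
            for label in self.subsets
        }
        return self


def run_screen(
    records: pd.DataFrame,
    subsets: Sequence[str] = SUBSET_LABELS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen every cause in a harmonized record frame across ``subsets``."""
    return GestationalAgeScreen(alpha=alpha, subsets=subsets).fit(records).results_
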