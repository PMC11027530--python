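"""Weekly age-at-death profiles, annual mortality trends, and the SIDS screens.

Two screens ask which harmonized cause groups look like sudden infant death
syndrome (SIDS):

* **Profile screen** — each cause's deaths are tallied by age-at-death week
  (0..52) and normalized to frequencies; a cause is flagged when the Pearson
  correlation between its frequency vector and the reference (SIDS) vector is
  at least 0.5.  This operationalizes "peaks in the third month of life like
  SIDS does" without hand-picking a window.
* **Trend screen** — each cause's annual death counts over the in-scope years
  are expressed as percent of that cause's mean level; a cause is flagged when
  its normalized series correlates *positively* with the reference's at
  two-sided p < 0.005.  This captures the post-1994 "Back to Sleep" drop.

Pearson p-values come from the exact t-transform with n−2 degrees of freedom
(`scipy.stats.pearsonr`); n differs between screens (53 weeks vs the number of
in-scope years) and is reported alongside every r.  Constant vectors have no
defined correlation and are excluded and logged, never silently flagged.
No multiple-testing correction is applied across causes — the screens use
per-cause thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "WeeklyProfile",
    "AnnualSeries",
    "ScreenSets",
    "weekly_profile",
    "weekly_profiles",
    "annual_series",
    "annual_series_all",
    "profile_screen",
    "trend_screen",
    "intersect_screens",
    "ProfileCorrelationScreen",
    "TrendCorrelationScreen",
]

N_WEEKS = 53  # age-at-death weeks 0..52

#: absolute slack used when testing r against an inclusive threshold, so that
#: a pair constructed to have r = 1/2 exactly is not lost to float rounding
R_THRESHOLD_TOL = 1e-12


@dataclass
class WeeklyProfile:
    """Normalized distribution of one cause's deaths over age-at-death weeks."""

    joined_id: str
    counts: np.ndarray  # length 53, int
    frequencies: np.ndarray = field(init=False)  # counts / total

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_WEEKS,):
            raise ValueError(f"counts must have length {N_WEEKS}")
        total = self.counts.sum()
        if total <= 0:
            raise ValueError(f"cause {self.joined_id!r}: no deaths to profile")
        self.frequencies = self.counts / total


@dataclass
class AnnualSeries:
    """One cause's yearly death counts as percent of its mean in-scope level."""

    joined_id: str
    years: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.years.shape != self.counts.shape:
            raise ValueError("years and counts must align")
        mean = self.counts.mean() if self.counts.size else 0.0
        if mean <= 0:
            raise ValueError(f"cause {self.joined_id!r}: all-zero annual counts")
        self.normalized = 100.0 * self.counts / mean


def weekly_profile(records: pd.DataFrame, joined_id: str = "") -> WeeklyProfile:
    """Tally one cause's records into a 53-week profile.

    ``records`` must carry ``age_at_death_weeks`` (see
    :func:`sidscreen.etl.add_derived_columns`); at least one record required.
    """
    if records.empty:
        raise ValueError(f"cause {joined_id!r}: cannot profile zero records")
    weeks = records["age_at_death_weeks"].to_numpy()
    counts = np.bincount(weeks, minlength=N_WEEKS)
    return WeeklyProfile(joined_id=joined_id, counts=counts)


def weekly_profiles(records: pd.DataFrame) -> dict[str, WeeklyProfile]:
    """Profiles for every joined cause in a harmonized record frame."""
    return {
        jid: weekly_profile(group, jid)
        for jid, group in records.groupby("joined_id", sort=True)
    }


def annual_series(
    records: pd.DataFrame, years: Sequence[int], joined_id: str = ""
) -> AnnualSeries:
    """Annual counts for one cause over the in-scope year axis (gap-aware).

    Years missing from ``years`` (e.g. the 1992–1994 archive gap) carry no
    value and do not enter the mean; in-scope years with no deaths count zero.
    """
    years = sorted(set(years))
    in_scope = records[records["year"].isin(years)]
    counts = (
        in_scope.groupby("year").size().reindex(years, fill_value=0).to_numpy()
    )
    return AnnualSeries(joined_id=joined_id, years=np.array(years), counts=counts)


def annual_series_all(
    records: pd.DataFrame, years: Sequence[int]
) -> dict[str, AnnualSeries]:
    out: dict[str, AnnualSeries] = {}
    for jid, group in records.groupby("joined_id", sort=True):
        if group["year"].isin(years).any():
            out[jid] = annual_series(group, years, jid)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(r, two-sided p, n) with p from the t-transform, t = r sqrt((n-2)/(1-r^2))."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


class ProfileCorrelationScreen(BaseEstimator):
    """Flag causes whose weekly death profile correlates with the reference's.

    Parameters
    ----------
    reference_id:
        Joined id of the reference cause (SIDS in the motivating analysis).
    threshold:
        Minimum Pearson r, inclusive.  Default 0.5.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per screened cause: joined_id, r, n, selected.
    selected_ : set[str]
        Causes with r >= threshold (always contains the reference: r = 1).
    excluded_ : list[str]
        Causes with constant frequency vectors (correlation undefined).
    """

    def __init__(self, reference_id: str = "", threshold: float = 0.5):
        self.reference_id = reference_id
        self.threshold = threshold

    def fit(self, X: Mapping[str, WeeklyProfile], y=None):
        if self.reference_id not in X:
            raise KeyError(f"reference cause {self.reference_id!r} has no profile")
        ref = X[self.reference_id].frequencies
        if np.ptp(ref) == 0:
            raise ValueError("reference profile is constant; correlation undefined")
        rows = []
        self.excluded_: list[str] = []
        for jid in sorted(X):
            freq = X[jid].frequencies
            if np.ptp(freq) == 0:
                self.excluded_.append(jid)
                logger.info("profile screen: %s constant, excluded", jid)
                continue
            if jid == self.reference_id:
                # x vs x: identically 1, no need to round-trip through floats
                r, p, n = 1.0, 0.0, len(freq)
            else:
                r, p, n = _pearson(freq, ref)
            rows.append(
                {
                    "joined_id": jid,
                    "r": r,
                    "p": p,
                    "n": n,
                    "selected": r >= self.threshold - R_THRESHOLD_TOL,
                }
            )
        self.results_ = pd.DataFrame(
            rows, columns=["joined_id", "r", "p", "n", "selected"]
        )
        self.selected_ = set(self.results_.loc[self.results_["selected"], "joined_id"])
        return self


class TrendCorrelationScreen(BaseEstimator):
    """Flag causes whose annual mortality trend tracks the reference's.

    Selection requires Pearson r > 0 with two-sided p < ``alpha`` between the
    normalized annual series and the reference's, over a shared year axis of at
    least 3 years.  Constant series are excluded (undefined r) and logged.

    Attributes mirror :class:`ProfileCorrelationScreen`.
    """

    def __init__(self, reference_id: str = "", alpha: float = 0.005):
        self.reference_id = reference_id
        self.alpha = alpha

    def fit(self, X: Mapping[str, AnnualSeries], y=None):
        if self.reference_id not in X:
            raise KeyError(f"reference cause {self.reference_id!r} has no series")
        ref = X[self.reference_id]
        if np.ptp(ref.normalized) == 0:
            raise ValueError("reference series is constant; correlation undefined")
        rows = []
        self.excluded_: list[str] = []
        for jid in sorted(X):
            series = X[jid]
            if not np.array_equal(series.years, ref.years):
                raise ValueError(
                    f"cause {jid!r} series year axis differs from the reference's"
                )
            if len(series.years) < 3:
                raise ValueError("trend screen needs at least 3 shared years")
            if np.ptp(series.normalized) == 0:
                self.excluded_.append(jid)
                logger.info("trend screen: %s constant, excluded", jid)
                continue
            if jid == self.reference_id:
                r, p, n = 1.0, 0.0, len(series.years)
            else:
                r, p, n = _pearson(series.normalized, ref.normalized)
            rows.append(
                {
                    "joined_id": jid,
                    "r": r,
                    "p": p,
                    "n": n,
                    "selected": (r > 0) and (p < self.alpha),
                }
            )
        self.results_ = pd.DataFrame(
            rows, columns=["joined_id", "r", "p", "n", "selected"]
        )
        self.selected_ = set(self.results_.loc[self.results_["selected"], "joined_id"])
        return self


@dataclass
class ScreenSets:
    """The two screen hit sets and their intersection.

    Whether the reference cause itself should be counted among "causes that
    look like the reference" is a reporting choice, so each set is exposed both
    with and without it.
    """

    reference_id: str
    profile_correlated: set[str]
    trend_correlated: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.profile_correlated & self.trend_correlated

    def without_reference(self, which: set[str]) -> set[str]:
        return which - {self.reference_id}


# ---------------------------------------------------------------------------
# thin functional wrappers


def profile_screen(
    profiles: Mapping[str, WeeklyProfile], reference_id: str, threshold: float = 0.5
) -> set[str]:
    """Causes whose profile has Pearson r >= ``threshold`` with the reference."""
    return (
        ProfileCorrelationScreen(reference_id=reference_id, threshold=threshold)
        .fit(profiles)
        .selected_
    )


def trend_screen(
    series: Mapping[str, AnnualSeries], reference_id: str, alpha: float = 0.005
) -> set[str]:
    """Causes with r > 0 and p < ``alpha`` against the reference trend."""
    return (
        TrendCorrelationScreen(reference_id=reference_id, alpha=alpha)
        .fit(series)
        .selected_
    )


def intersect_screens(sets: ScreenSets) -> set[str]:
    """Causes passing both screens — the candidates for further investigation."""
    return sets.intersection
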