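"""Synthetic linked birth–infant death cohorts with planted statistical structure.

Real linked birth–infant death files (one record per infant death, carrying the
calendar year, gestational age at birth, age at death and an ICD-coded cause)
cannot be redistributed, so this module generates cohorts whose per-cause weekly
age-at-death profiles, annual mortality trends and gestational-age/age-at-death
coupling are all *known by construction*.  Every downstream stage — code
harmonization, the profile and trend correlation screens, the gestational-age
regression screen — can therefore be tested against planted ground truth.

Counts are deterministic quotas per (cause, year), not Poisson draws: the
realized number of deaths equals the configured expectation exactly, which
makes rare-cause filtering and trend tests sharp.  A record's age at death is
sampled on the week scale as

    round( peak_week + slope * (g - 40) + eps ),   eps ~ N(0, hypot(spread, noise_sd))

clamped to [0, 52] and then placed uniformly on a day within that week.  The
two dispersion parameters (the cause's intrinsic weekly spread and the
residual gestational-age noise) act as independent Gaussian components, so
their convolution has SD hypot(spread, noise_sd).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .harmonize import normalize_code

__all__ = [
    "CauseSpec",
    "CohortConfig",
    "GemRow",
    "default_gestage_weights",
    "generate_cohort",
    "generate_gem_tables",
    "write_records_delimited",
    "read_records_delimited",
    "write_gem_table",
]

#: Columns of the canonical death-record frame used throughout the package.
RECORD_COLUMNS = [
    "year",
    "gestational_age_weeks",
    "age_at_death_days",
    "cause_code",
    "icd_version",
]

GESTAGE_MIN_WEEK = 17
GESTAGE_MAX_WEEK = 47
MAX_DEATH_WEEK = 52  # infant deaths: age_at_death_days in [0, 364]
ICD10_SWITCH_YEAR = 1999


def default_gestage_weights() -> dict[int, float]:
    """Gestational-age distribution used when a config supplies none.

    A stand-in for the (unpublished) empirical distribution of gestational age
    among U.S. infant deaths: mass concentrated at term (39–40 weeks), a
    moderate late-preterm shoulder and a thin extreme-preterm tail down to
    week 17.  Values are relative weights, normalized on use.
    """
    raw = {w: 0.05 for w in range(17, 28)}
    raw.update({w: 0.15 for w in range(28, 32)})
    raw.update({32: 0.4, 33: 0.4, 34: 1.0, 35: 1.5, 36: 3.0})
    raw.update({37: 7.0, 38: 12.0, 39: 22.0, 40: 30.0})
    raw.update({41: 12.0, 42: 6.0, 43: 1.5, 44: 0.5, 45: 0.2, 46: 0.1, 47: 0.05})
    total = sum(raw.values())
    return {w: v / total for w, v in sorted(raw.items())}


@dataclass
class CauseSpec:
    """One cause of death and the statistical structure planted for it.

    Parameters
    ----------
    name:
        Human-readable label; used for error messages and ground-truth bookkeeping.
    icd9_codes, icd10_codes:
        Raw ICD code strings for this cause (normalized on construction:
        uppercased, periods stripped).  A record drawn in an ICD-9 year picks
        uniformly from ``icd9_codes``, and analogously for ICD-10.
    annual_counts:
        Expected number of deaths per calendar year.  Realized counts equal
        these values exactly (quota semantics).
    profile_peak_week:
        Age-at-death week (0-based) of modal mortality for a term birth.
    profile_spread:
        SD (weeks) of the cause's intrinsic weekly death distribution; > 0.
    gestage_slope:
        Planted change in age at death (weeks) per +1 week of gestation.
    gestage_noise_sd:
        Residual SD (weeks) of age at death around the gestational-age trend.
    """

    name: str
    icd9_codes: list[str] = field(default_factory=list)
    icd10_codes: list[str] = field(default_factory=list)
    annual_counts: dict[int, int] = field(default_factory=dict)
    profile_peak_week: float = 11.0
    profile_spread: float = 4.0
    gestage_slope: float = 0.0
    gestage_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.icd9_codes = [normalize_code(c) for c in self.icd9_codes]
        self.icd10_codes = [normalize_code(c) for c in self.icd10_codes]
        if any(n < 0 for n in self.annual_counts.values()):
            raise ValueError(f"cause {self.name!r}: annual_counts must be >= 0")
        if not 0 <= self.profile_peak_week <= MAX_DEATH_WEEK:
            raise ValueError(f"cause {self.name!r}: profile_peak_week outside [0, 52]")
        if self.profile_spread <= 0:
            raise ValueError(f"cause {self.name!r}: profile_spread must be > 0")
        if self.gestage_noise_sd < 0:
            raise ValueError(f"cause {self.name!r}: gestage_noise_sd must be >= 0")

    def codes_for_version(self, icd_version: int) -> list[str]:
        return self.icd9_codes if icd_version == 9 else self.icd10_codes


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``years`` may contain gaps (the real archive is missing 1992–1994).
    ``gestage_weights`` maps gestational week -> probability; support must lie
    within [17, 47].  All randomness flows from the single ``seed``: samplers
    draw from one seeded stream in a fixed order (causes in list order, years
    ascending), so a config is a bit-reproducible fixture.
    """

    causes: list[CauseSpec]
    years: list[int]
    gestage_weights: dict[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.gestage_weights is None:
            self.gestage_weights = default_gestage_weights()
        weeks = sorted(self.gestage_weights)
        if any(w < GESTAGE_MIN_WEEK or w > GESTAGE_MAX_WEEK for w in weeks):
            raise ValueError("gestage_weights support must lie within [17, 47]")
        vals = np.array([self.gestage_weights[w] for w in weeks], dtype=float)
        if (vals < 0).any():
            raise ValueError("gestage_weights must be nonnegative")
        total = vals.sum()
        if not np.isclose(total, 1.0):
            if total <= 0:
                raise ValueError("gestage_weights must have positive mass")
            self.gestage_weights = {w: v / total for w, v in zip(weeks, vals)}


def _icd_version_for_year(year: int) -> int:
    return 9 if year < ICD10_SWITCH_YEAR else 10


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one death-record frame from ``config``.

    Returns a DataFrame with columns ``year, gestational_age_weeks,
    age_at_death_days, cause_code, icd_version``; exactly
    ``sum(annual_counts over config.years)`` rows.

    Raises
    ------
    ValueError
        If a cause has deaths scheduled in a year whose ICD version it has no
        codes for.
    """
    rng = np.random.default_rng(config.seed)
    weeks = np.array(sorted(config.gestage_weights), dtype=np.int64)
    probs = np.array([config.gestage_weights[w] for w in weeks], dtype=float)

    frames: list[pd.DataFrame] = []
    for cause in config.causes:
        total_sd = float(np.hypot(cause.profile_spread, cause.gestage_noise_sd))
        for year in config.years:
            n = int(cause.annual_counts.get(year, 0))
            if n == 0:
                continue
            version = _icd_version_for_year(year)
            codes = cause.codes_for_version(version)
            if not codes:
                raise ValueError(
                    f"cause {cause.name!r} has {n} deaths in {year} but no "
                    f"ICD-{version} codes"
                )
            g = rng.choice(weeks, size=n, p=probs)
            mean_week = (
                cause.profile_peak_week + cause.gestage_slope * (g - 40.0)
            )
            week = np.rint(mean_week + rng.normal(0.0, total_sd, size=n))
            week = np.clip(week, 0, MAX_DEATH_WEEK).astype(np.int64)
            # week 52 holds a single day (364); earlier weeks hold 7 days
            day_span = np.where(week == MAX_DEATH_WEEK, 1, 7)
            days = week * 7 + rng.integers(0, day_span)
            code_idx = rng.integers(0, len(codes), size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "year": np.full(n, year, dtype=np.int64),
                        "gestational_age_weeks": g,
                        "age_at_death_days": days,
                        "cause_code": np.array(codes, dtype=object)[code_idx],
                        "icd_version": np.full(n, version, dtype=np.int64),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            {c: pd.Series(dtype=("object" if c == "cause_code" else "int64"))
             for c in RECORD_COLUMNS}
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# GEM equivalence-table generation


@dataclass(frozen=True)
class GemRow:
    """One line of a GEM crosswalk file: source code, target code, flag string."""

    source: str
    target: str
    flags: str = "00000"


def _component_nodes(
    icd9: Sequence[str], icd10: Sequence[str]
) -> frozenset[tuple[str, int]]:
    return frozenset(
        [(normalize_code(c), 9) for c in icd9]
        + [(normalize_code(c), 10) for c in icd10]
    )


def generate_gem_tables(
    components_spec: Sequence[tuple[Sequence[str], Sequence[str]]],
    n_icd9: int | None = None,
    n_icd10: int | None = None,
    seed: int = 0,
    extra_edge_prob: float = 0.3,
) -> tuple[list[GemRow], list[GemRow], list[frozenset[tuple[str, int]]]]:
    """Emit forward (10→9) and backward (9→10) GEM tables with known components.

    ``components_spec`` lists (icd9 codes, icd10 codes) per intended connected
    component; subsets must be disjoint across components.  Emitted rows span
    each component (guaranteed connectivity) plus random extra within-component
    cross-version pairs; no row ever links two distinct components.  If
    ``n_icd9``/``n_icd10`` exceed the number of codes used by the spec, filler
    codes are added as mapped-nowhere singletons.

    Returns ``(forward_rows, backward_rows, ground_truth_components)`` where the
    ground truth is a list of frozensets of ``(code, icd_version)`` pairs.
    """
    rng = np.random.default_rng(seed)
    seen9: set[str] = set()
    seen10: set[str] = set()
    truth: list[frozenset[tuple[str, int]]] = []
    forward: list[GemRow] = []
    backward: list[GemRow] = []

    for icd9, icd10 in components_spec:
        c9 = [normalize_code(c) for c in icd9]
        c10 = [normalize_code(c) for c in icd10]
        if seen9 & set(c9) or seen10 & set(c10):
            raise ValueError("component subsets overlap across components")
        seen9 |= set(c9)
        seen10 |= set(c10)
        truth.append(_component_nodes(c9, c10))
        if not c9 or not c10:
            # one-sided components cannot carry cross-version edges; they are
            # legal only as singletons
            if len(c9) + len(c10) > 1:
                raise ValueError(
                    "a multi-code component needs codes on both ICD sides"
                )
            continue
        # spanning pattern: every ICD-9 code maps to the first ICD-10 code,
        # and the first ICD-9 code maps to every remaining ICD-10 code
        pairs = {(a, c10[0]) for a in c9} | {(c9[0], b) for b in c10[1:]}
        for a, b in itertools.product(c9, c10):
            if (a, b) not in pairs and rng.random() < extra_edge_prob:
                pairs.add((a, b))
        for a, b in sorted(pairs):
            flags = f"{int(rng.random() < 0.5)}0000"
            if rng.random() < 0.5:
                forward.append(GemRow(source=b, target=a, flags=flags))
            else:
                backward.append(GemRow(source=a, target=b, flags=flags))

    if n_icd9 is not None:
        for i in range(len(seen9), n_icd9):
            code = f"75{i:03d}"
            if code not in seen9:
                truth.append(frozenset({(code, 9)}))
    if n_icd10 is not None:
        for i in range(len(seen10), n_icd10):
            code = f"Q{i:03d}"
            if code not in seen10:
                truth.append(frozenset({(code, 10)}))
    return forward, backward, truth


# ---------------------------------------------------------------------------
# Writers for the text dialects the rest of the pipeline reads


def write_records_delimited(records: pd.DataFrame, path) -> None:
    """Write a record frame as the tab-separated dialect ``cohort_etl`` reads."""
    records.to_csv(path, sep="\t", index=False)


def read_records_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cause_code": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"delimited record file missing columns: {sorted(missing)}")
    return df


def write_gem_table(rows: Iterable[GemRow], path) -> None:
    """Write GEM rows as whitespace-separated ``source target flags`` text."""
    with open(path, "w") as fh:
        fh.write("# source target flags\n")
        for row in rows:
            fh.write(f"{row.source} {row.target} {row.flags}\n")
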