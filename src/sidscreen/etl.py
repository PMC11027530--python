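"""Read raw vital-statistics records and derive the analysis fields.

The national linked birth–infant death archive ships one fixed-width file per
birth cohort year, with column layouts that drift across years; a
:class:`LayoutSpec` describes one such layout (column spans plus the sentinel
codes that mean "unknown").  The module also reads the package's own
tab-separated record dialect, converts day-scale ages to 0-based weeks, assigns
"Back to Sleep" eras and ICD revisions from the calendar year, and applies the
rare-cause filter.

Conventions fixed here and used everywhere downstream:

* age week ``w`` covers days ``[7w, 7w+7)`` (0-based, floor division);
* ICD-9 before 1999, ICD-10 from 1999 on;
* eras: before = 1986–1991, during = 1995–1999, after = 2000–2005, everything
  else (including the missing 1992–1994 archive years) excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .harmonize import normalize_code

__all__ = [
    "FieldSpec",
    "LayoutSpec",
    "DEMO_LAYOUT",
    "read_records",
    "write_records_fixed_width",
    "days_to_weeks",
    "assign_era",
    "assign_icd_version",
    "add_derived_columns",
    "in_scope_years",
    "filter_rare_causes",
    "ERA_RANGES",
]

ICD10_SWITCH_YEAR = 1999

#: era label -> (first year, last year), inclusive
ERA_RANGES: dict[str, tuple[int, int]] = {
    "before": (1986, 1991),
    "during": (1995, 1999),
    "after": (2000, 2005),
}


@dataclass(frozen=True)
class FieldSpec:
    """One fixed-width field: 0-based half-open column span plus unknown codes."""

    start: int
    stop: int
    unknown: frozenset[str] = frozenset()

    def extract(self, line: str) -> str:
        return line[self.start : self.stop].strip()


@dataclass
class LayoutSpec:
    """Fixed-width layout for a span of file years.

    ``fields`` must provide ``year``, ``gestational_age_weeks``,
    ``age_at_death_days`` and ``cause_code``; spans may not overlap.
    """

    year_range: tuple[int, int]
    line_width: int
    fields: dict[str, FieldSpec] = field(default_factory=dict)

    REQUIRED = ("year", "gestational_age_weeks", "age_at_death_days", "cause_code")

    def __post_init__(self) -> None:
        missing = [name for name in self.REQUIRED if name not in self.fields]
        if missing:
            raise ValueError(f"layout missing required fields: {missing}")
        spans = sorted((f.start, f.stop) for f in self.fields.values())
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("layout fields overlap")
        if any(f.stop > self.line_width for f in self.fields.values()):
            raise ValueError("field span exceeds line width")


#: Example layout matching the synthetic generator's fixed-width writer:
#: year cols 1-4, gestation 5-6 ("99" unknown), age in days 7-9 ("999"
#: unknown), cause code 10-15.
DEMO_LAYOUT = LayoutSpec(
    year_range=(1983, 2011),
    line_width=15,
    fields={
        "year": FieldSpec(0, 4),
        "gestational_age_weeks": FieldSpec(4, 6, frozenset({"99"})),
        "age_at_death_days": FieldSpec(6, 9, frozenset({"999"})),
        "cause_code": FieldSpec(9, 15),
    },
)


def read_records(stream, layout: LayoutSpec) -> tuple[pd.DataFrame, int]:
    """Parse a fixed-width file into the canonical record frame.

    Returns ``(records, n_dropped)`` where dropped rows are those whose
    gestation or age field holds an unknown-value sentinel (the archive codes
    missing data in-band rather than leaving blanks).  A line of the wrong
    width raises a ``ValueError`` with its line number.
    """
    if isinstance(stream, str):
        stream = iter(stream.splitlines())
    rows = []
    dropped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if len(line) != layout.line_width:
            raise ValueError(
                f"line {lineno}: width {len(line)} does not match layout width "
                f"{layout.line_width}"
            )
        values = {name: spec.extract(line) for name, spec in layout.fields.items()}
        try:
            gest = int(values["gestational_age_weeks"])
            age = int(values["age_at_death_days"])
        except ValueError:
            gest = age = None
        if (
            gest is None
            or age is None
            or values["gestational_age_weeks"] in layout.fields["gestational_age_weeks"].unknown
            or values["age_at_death_days"] in layout.fields["age_at_death_days"].unknown
        ):
            dropped += 1
            continue
        year = int(values["year"])
        rows.append(
            {
                "year": year,
                "gestational_age_weeks": gest,
                "age_at_death_days": age,
                "cause_code": normalize_code(values["cause_code"]),
                "icd_version": assign_icd_version(year),
            }
        )
    columns = ["year", "gestational_age_weeks", "age_at_death_days",
               "cause_code", "icd_version"]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        df = df.astype({c: "int64" for c in columns if c != "cause_code"})
    return df, dropped


def write_records_fixed_width(records: pd.DataFrame, path, layout: LayoutSpec = DEMO_LAYOUT) -> None:
    """Write records in the fixed-width dialect ``read_records`` accepts."""
    f = layout.fields
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            line = [" "] * layout.line_width
            def put(name: str, text: str, zero_pad: bool) -> None:
                spec = f[name]
                width = spec.stop - spec.start
                if len(text) > width:
                    raise ValueError(f"value {text!r} too wide for field {name}")
                text = text.rjust(width, "0") if zero_pad else text.ljust(width)
                line[spec.start : spec.stop] = text
            put("year", str(row.year), True)
            put("gestational_age_weeks", str(row.gestational_age_weeks), True)
            put("age_at_death_days", str(row.age_at_death_days), True)
            put("cause_code", str(row.cause_code), False)
            fh.write("".join(line) + "\n")


def days_to_weeks(age_days: int) -> int:
    """Convert age at death from days to 0-based completed weeks (floor)."""
    if not 0 <= age_days <= 364:
        raise ValueError(f"age_at_death_days must be in [0, 364], got {age_days}")
    return int(age_days) // 7


def assign_era(year: int) -> str:
    """Era of the "Back to Sleep" campaign a year falls in (or ``excluded``)."""
    for label, (lo, hi) in ERA_RANGES.items():
        if lo <= year <= hi:
            return label
    return "excluded"


def assign_icd_version(year: int) -> int:
    """ICD revision used for the year: 9 before 1999, 10 from 1999 on."""
    return 9 if year < ICD10_SWITCH_YEAR else 10


def add_derived_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``age_at_death_weeks``, ``era`` and (if absent) ``icd_version``."""
    out = records.copy()
    bad = ~out["age_at_death_days"].between(0, 364)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} records have age_at_death_days outside [0, 364]"
        )
    out["age_at_death_weeks"] = out["age_at_death_days"] // 7
    out["era"] = out["year"].map(assign_era)
    if "icd_version" not in out.columns:
        out["icd_version"] = out["year"].map(assign_icd_version)
    return out


def in_scope_years(era_ranges: dict[str, tuple[int, int]] = ERA_RANGES) -> list[int]:
    """All years covered by the era definitions, ascending."""
    years: set[int] = set()
    for lo, hi in era_ranges.values():
        years.update(range(lo, hi + 1))
    return sorted(years)


def filter_rare_causes(
    records: pd.DataFrame,
    years: Iterable[int],
    threshold: float = 20.0,
    per_year: bool = False,
) -> set[str]:
    """Joined causes frequent enough to describe statistically.

    A cause is retained iff its mean annual death count over ``years`` is
    strictly greater than ``threshold`` (years with no deaths count as zero).
    With ``per_year=True`` the count in *every* year must exceed the threshold
    instead — a stricter sensitivity variant.
    """
    years = sorted(set(years))
    if not years:
        raise ValueError("year scope must be non-empty")
    in_scope = records[records["year"].isin(years)]
    counts = (
        in_scope.groupby(["joined_id", "year"]).size().unstack(fill_value=0)
        .reindex(columns=years, fill_value=0)
    )
    if per_year:
        keep = counts.gt(threshold).all(axis=1)
    else:
        keep = counts.mean(axis=1).gt(threshold)
    return set(counts.index[keep])
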