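"""One-command orchestration: ETL → harmonization → screens → report tables.

`run_pipeline` executes the whole analysis from a single
:class:`PipelineConfig`, in synthetic mode (generate a cohort and GEM tables
with planted structure) or files mode (read a delimited or fixed-width record
file plus real GEM text files).  All stage outputs are written as delimited
text under the configured output directory together with a JSON manifest
(seed, thresholds, per-stage counts, SHA-256 digests of every table), so a
rerun with the same config and seed is byte-identical and each stage can be
re-run from its predecessor's on-disk outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import etl
from .demo import DEMO_REFERENCE_CODE, demo_cohort_config, demo_components_spec
from .gestage import SUBSET_LABELS, GestationalAgeScreen, per_gestweek_summary
from .harmonize import (
    CodeHarmonizer,
    normalize_code,
    parse_gem_file,
    write_component_table,
)
from .profiles import (
    ProfileCorrelationScreen,
    ScreenSets,
    TrendCorrelationScreen,
    annual_series_all,
    weekly_profiles,
)
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_gem_tables,
    write_gem_table,
    write_records_delimited,
    read_records_delimited,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo_pipeline_config"]

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``mode`` is ``"synthetic"`` (generate ``cohort`` and GEM tables from
    ``components_spec``) or ``"files"`` (read ``records_path`` — delimited, or
    fixed-width when a layout is given — plus ``gem_forward_path`` /
    ``gem_backward_path``).  Screen thresholds default to the analysis
    constants: profile r >= 0.5, trend p < 0.005, regression p < 0.05,
    rare-cause cutoff 20 deaths/year, eras 1986–1991 / 1995–1999 / 2000–2005,
    ICD switch at 1999.
    """

    out_dir: str | Path
    mode: str = "synthetic"
    seed: int = 0
    # synthetic mode
    cohort: CohortConfig | None = None
    components_spec: list[tuple[list[str], list[str]]] | None = None
    # files mode
    records_path: str | Path | None = None
    gem_forward_path: str | Path | None = None
    gem_backward_path: str | Path | None = None
    layout: etl.LayoutSpec | None = None  # None -> delimited dialect
    # screening constants
    reference_code: str = DEMO_REFERENCE_CODE
    reference_icd_version: int = 10
    profile_r_threshold: float = 0.5
    trend_alpha: float = 0.005
    regression_alpha: float = 0.05
    rare_cutoff: float = 20.0
    era_ranges: dict[str, tuple[int, int]] = dc_field(
        default_factory=lambda: dict(etl.ERA_RANGES)
    )
    subsets: Sequence[str] = SUBSET_LABELS

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.cohort is None:
            raise ValueError("synthetic mode needs a cohort config")
        if self.mode == "files" and (
            self.records_path is None
            or self.gem_forward_path is None
            or self.gem_backward_path is None
        ):
            raise ValueError("files mode needs records and both GEM paths")
        for name in ("trend_alpha", "regression_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not -1 < self.profile_r_threshold <= 1:
            raise ValueError("profile_r_threshold must lie in (-1, 1]")
        if self.rare_cutoff < 0:
            raise ValueError("rare_cutoff must be >= 0")
        spans = sorted(self.era_ranges.values())
        for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError("era ranges overlap")
        for s in self.subsets:
            if s not in SUBSET_LABELS:
                raise ValueError(f"unknown subset label {s!r}")


def demo_pipeline_config(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Pipeline config for the bundled planted demonstration cohort."""
    return PipelineConfig(
        out_dir=out_dir,
        mode="synthetic",
        seed=seed,
        cohort=demo_cohort_config(seed=seed),
        components_spec=demo_components_spec(),
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _era_years(era_ranges: dict[str, tuple[int, int]]) -> list[int]:
    years: set[int] = set()
    for lo, hi in era_ranges.values():
        years.update(range(lo, hi + 1))
    return sorted(years)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screening analysis; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage: input acquisition -----------------------------------------
    if config.mode == "synthetic":
        records = generate_cohort(config.cohort)
        forward_rows, backward_rows, _truth = generate_gem_tables(
            config.components_spec or [], seed=config.seed
        )
        write_records_delimited(records, out / "records_raw.tsv")
        write_gem_table(forward_rows, out / "gem_forward.txt")
        write_gem_table(backward_rows, out / "gem_backward.txt")
        gem_forward_path = out / "gem_forward.txt"
        gem_backward_path = out / "gem_backward.txt"
    else:
        if config.layout is not None:
            with open(config.records_path) as fh:
                records, n_dropped = etl.read_records(fh, config.layout)
            counts["records_dropped_unparseable"] = n_dropped
        else:
            records = read_records_delimited(config.records_path)
        gem_forward_path = Path(config.gem_forward_path)
        gem_backward_path = Path(config.gem_backward_path)
    counts["records_read"] = len(records)
    if records.empty:
        raise ValueError("stage etl: no records to analyze")

    # --- stage: harmonization ---------------------------------------------
    with open(gem_forward_path) as fh:
        entries = parse_gem_file(fh, "forward")
    with open(gem_backward_path) as fh:
        entries += parse_gem_file(fh, "backward")
    harmonizer = CodeHarmonizer().fit(records, gem_entries=entries)
    write_component_table(harmonizer.components_, out / "components.tsv")
    counts["gem_entries"] = len(entries)
    counts["joined_groups"] = len(harmonizer.components_)
    harmonized = harmonizer.transform(records)
    harmonized = etl.add_derived_columns(harmonized)
    harmonized = harmonized.sort_values(
        ["joined_id", "year", "gestational_age_weeks", "age_at_death_days"],
        ignore_index=True,
    )
    _write(
        harmonized[
            ["year", "era", "icd_version", "gestational_age_weeks",
             "age_at_death_weeks", "joined_id"]
        ],
        out / "records_harmonized.tsv",
    )

    ref_key = (normalize_code(config.reference_code), config.reference_icd_version)
    if ref_key not in harmonizer.code_to_group_:
        raise ValueError(
            f"stage harmonization: reference code {ref_key} not observed in cohort"
        )
    reference_id = harmonizer.code_to_group_[ref_key]

    # --- stage: scope + rare-cause filter ----------------------------------
    years = _era_years(config.era_ranges)
    in_scope = harmonized[harmonized["era"] != "excluded"]
    retained = etl.filter_rare_causes(in_scope, years, threshold=config.rare_cutoff)
    counts["records_in_scope"] = len(in_scope)
    counts["causes_retained"] = len(retained)
    counts["causes_filtered_rare"] = in_scope["joined_id"].nunique() - len(retained)
    if reference_id not in retained:
        raise ValueError("stage filter: reference cause removed by rare-cause filter")
    analysis = in_scope[in_scope["joined_id"].isin(retained)]

    # --- stage: profile + trend screens ------------------------------------
    profiles = weekly_profiles(analysis)
    prof_rows = [
        {"joined_id": jid, "week": wk, "count": int(p.counts[wk]),
         "frequency": p.frequencies[wk]}
        for jid, p in sorted(profiles.items())
        for wk in range(len(p.counts))
    ]
    _write(pd.DataFrame(prof_rows), out / "weekly_profiles.tsv")

    series = annual_series_all(analysis, years)
    ser_rows = [
        {"joined_id": jid, "year": int(y), "count": int(c), "normalized": nv}
        for jid, s in sorted(series.items())
        for y, c, nv in zip(s.years, s.counts, s.normalized)
    ]
    _write(pd.DataFrame(ser_rows), out / "annual_series.tsv")

    prof_screen = ProfileCorrelationScreen(
        reference_id=reference_id, threshold=config.profile_r_threshold
    ).fit(profiles)
    trend = TrendCorrelationScreen(
        reference_id=reference_id, alpha=config.trend_alpha
    ).fit(series)
    sets = ScreenSets(
        reference_id=reference_id,
        profile_correlated=prof_screen.selected_,
        trend_correlated=trend.selected_,
    )

    verdict = (
        prof_screen.results_[["joined_id", "r", "n"]]
        .rename(columns={"r": "r_profile", "n": "n_profile"})
        .merge(
            trend.results_[["joined_id", "r", "p", "n"]].rename(
                columns={"r": "r_trend", "p": "p_trend", "n": "n_trend"}
            ),
            on="joined_id",
            how="outer",
        )
        .sort_values("joined_id", ignore_index=True)
    )
    verdict["in_profile_set"] = verdict["joined_id"].isin(sets.profile_correlated)
    verdict["in_trend_set"] = verdict["joined_id"].isin(sets.trend_correlated)
    verdict["in_intersection"] = verdict["joined_id"].isin(sets.intersection)
    _write(verdict, out / "screen_verdicts.tsv")

    # --- stage: gestational-age screen --------------------------------------
    gest = GestationalAgeScreen(
        alpha=config.regression_alpha, subsets=config.subsets
    ).fit(analysis)
    _write(gest.results_, out / "gestage_results.tsv")
    summary_rows = []
    for jid, group in analysis.groupby("joined_id", sort=True):
        tbl = per_gestweek_summary(group)
        tbl.insert(0, "joined_id", jid)
        summary_rows.append(tbl)
    _write(pd.concat(summary_rows, ignore_index=True), out / "gestweek_summary.tsv")

    # --- manifest -----------------------------------------------------------
    tables = sorted(
        p.name for p in out.iterdir()
        if p.suffix in (".tsv", ".txt") and p.is_file()
    )
    manifest = {
        "package_version": _pkg_version("sidscreen"),
        "mode": config.mode,
        "seed": config.seed,
        "reference_joined_id": reference_id,
        "thresholds": {
            "profile_r": config.profile_r_threshold,
            "trend_alpha": config.trend_alpha,
            "regression_alpha": config.regression_alpha,
            "rare_cutoff": config.rare_cutoff,
        },
        "era_ranges": {k: list(v) for k, v in config.era_ranges.items()},
        "stages": ["etl", "harmonization", "filter", "profiles", "gestage"],
        "counts": counts,
        "screen_sets": {
            "profile_correlated": sorted(sets.profile_correlated),
            "trend_correlated": sorted(sets.trend_correlated),
            "intersection": sorted(sets.intersection),
            "profile_correlated_excl_reference": sorted(
                sets.without_reference(sets.profile_correlated)
            ),
            "trend_correlated_excl_reference": sorted(
                sets.without_reference(sets.trend_correlated)
            ),
            "intersection_excl_reference": sorted(
                sets.without_reference(sets.intersection)
            ),
            "gestage_passed": {
                label: sorted(ids) for label, ids in gest.passed_.items()
            },
        },
        "output_digests": {name: _digest(out / name) for name in tables},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# YAML config loading (CLI surface)


def cohort_config_from_dict(data: dict) -> CohortConfig:
    from .synthetic import CauseSpec

    causes = [CauseSpec(**c) for c in data["causes"]]
    return CohortConfig(
        causes=causes,
        years=list(data["years"]),
        gestage_weights=(
            {int(k): float(v) for k, v in data["gestage_weights"].items()}
            if data.get("gestage_weights")
            else None
        ),
        seed=int(data.get("seed", 0)),
    )


def pipeline_config_from_yaml(path: str | Path, out_dir: str | Path | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (see README for the schema)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kwargs = dict(data)
    if out_dir is not None:
        kwargs["out_dir"] = out_dir
    if "cohort" in kwargs and kwargs["cohort"] is not None:
        kwargs["cohort"] = cohort_config_from_dict(kwargs["cohort"])
    if "era_ranges" in kwargs and kwargs["era_ranges"] is not None:
        kwargs["era_ranges"] = {
            k: tuple(v) for k, v in kwargs["era_ranges"].items()
        }
    if kwargs.get("components_spec"):
        kwargs["components_spec"] = [
            (list(a), list(b)) for a, b in kwargs["components_spec"]
        ]
    return PipelineConfig(**kwargs)
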