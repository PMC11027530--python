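"""The documented synthetic demonstration cohort and its planted ground truth.

This config is the package's end-to-end fixture: eight causes over the
1986–2005 era years (with the 1992–1994 archive gap), designed so that each
screening outcome is known by construction:

* ``sids`` — the reference: age-at-death peak near week 11, a steep
  "Back to Sleep"-like drop in annual counts, and a planted negative
  gestational-age slope (−0.6 weeks/week).
* ``cardiac_arrest`` and ``viral_pneumonia`` — planted to pass **both**
  correlation screens: same profile shape as the reference and annual counts
  exactly proportional to the reference's (so the normalized trends coincide);
  gestational-age slope planted *positive*, so they never pass that screen.
* ``acute_bronchiolitis`` — profile screen only: SIDS-like weekly profile but a
  rising annual trend.
* ``congenital_heart`` — trend screen only: proportional annual decline but a
  late (week ~35) death profile.
* ``enterocolitis`` — the **only** non-reference cause passing the
  gestational-age screen (planted slope −0.6); its profile peaks near week 30
  and its annual counts are constant (degenerate for the trend screen).
* ``perinatal_respiratory`` — passes nothing: mid-range profile, constant
  counts, positive slope.
* ``rare_metabolic`` — 10 deaths/year, removed by the >20 cases/year filter.

Null gestational-age slopes are planted at +0.3 rather than 0 so that "does
not pass" is essentially sure rather than a 97.5% event.  Joined-group ids
below follow the smallest-member-code rule used by the harmonizer.
"""

from __future__ import annotations

from .synthetic import CauseSpec, CohortConfig

__all__ = [
    "demo_cohort_config",
    "demo_components_spec",
    "demo_planted_truth",
    "DEMO_YEARS",
    "DEMO_REFERENCE_CODE",
]

#: era years only: 1986–1991, 1995–1999, 2000–2005 (1992–1994 missing)
DEMO_YEARS = list(range(1986, 1992)) + list(range(1995, 2006))

#: raw reference code (SIDS, ICD-10); resolves to joined id "7980"
DEMO_REFERENCE_CODE = "R95"

# reference annual counts: steep decline, all values even so that
# proportional causes at exactly half the level stay integral
_SIDS_COUNTS = {
    1986: 520, 1987: 500, 1988: 480, 1989: 460, 1990: 440, 1991: 420,
    1995: 300, 1996: 280, 1997: 260, 1998: 240, 1999: 220,
    2000: 200, 2001: 190, 2002: 180, 2003: 170, 2004: 160, 2005: 150,
}
_HALF = {y: n // 2 for y, n in _SIDS_COUNTS.items()}
_RISING = {y: 60 + 10 * i for i, y in enumerate(DEMO_YEARS)}
_FLAT = {y: 100 for y in DEMO_YEARS}
_RARE = {y: 10 for y in DEMO_YEARS}


def demo_cohort_config(seed: int = 0) -> CohortConfig:
    """The planted demonstration cohort (see module docstring for the design)."""
    causes = [
        CauseSpec(
            name="sids",
            icd9_codes=["798.0"], icd10_codes=["R95"],
            annual_counts=dict(_SIDS_COUNTS),
            profile_peak_week=11, profile_spread=4,
            gestage_slope=-0.6, gestage_noise_sd=8,
        ),
        CauseSpec(
            name="cardiac_arrest",
            icd9_codes=["427.5"], icd10_codes=["I46.9"],
            annual_counts=dict(_HALF),
            profile_peak_week=11, profile_spread=4,
            gestage_slope=0.3, gestage_noise_sd=8,
        ),
        CauseSpec(
            name="viral_pneumonia",
            icd9_codes=["480.9"], icd10_codes=["J12.9"],
            annual_counts=dict(_HALF),
            profile_peak_week=11, profile_spread=4,
            gestage_slope=0.3, gestage_noise_sd=8,
        ),
        CauseSpec(
            name="acute_bronchiolitis",
            icd9_codes=["466.1"], icd10_codes=["J21.9"],
            annual_counts=dict(_RISING),
            profile_peak_week=11, profile_spread=4,
            gestage_slope=0.3, gestage_noise_sd=8,
        ),
        CauseSpec(
            name="congenital_heart",
            icd9_codes=["746.9"], icd10_codes=["Q24.9"],
            annual_counts=dict(_HALF),
            profile_peak_week=35, profile_spread=4,
            gestage_slope=0.3, gestage_noise_sd=4,
        ),
        CauseSpec(
            name="enterocolitis",
            icd9_codes=["777.5"], icd10_codes=["P77"],
            annual_counts=dict(_FLAT),
            profile_peak_week=30, profile_spread=3,
            gestage_slope=-0.6, gestage_noise_sd=4,
        ),
        CauseSpec(
            name="perinatal_respiratory",
            icd9_codes=["770.9"], icd10_codes=["P27.9"],
            annual_counts=dict(_FLAT),
            profile_peak_week=25, profile_spread=3,
            gestage_slope=0.3, gestage_noise_sd=4,
        ),
        CauseSpec(
            name="rare_metabolic",
            icd9_codes=["277.0"], icd10_codes=["E84.9"],
            annual_counts=dict(_RARE),
            profile_peak_week=11, profile_spread=4,
            gestage_slope=0.3, gestage_noise_sd=8,
        ),
    ]
    return CohortConfig(causes=causes, years=DEMO_YEARS, seed=seed)


def demo_components_spec() -> list[tuple[list[str], list[str]]]:
    """GEM component spec pairing each cause's ICD-9 and ICD-10 codes."""
    return [
        (cause.icd9_codes, cause.icd10_codes)
        for cause in demo_cohort_config().causes
    ]


def demo_planted_truth() -> dict[str, set[str]]:
    """Ground-truth screen outcomes, by construction (joined ids, ref excluded).

    Keys: ``profile`` (r >= 0.5 vs reference), ``trend`` (r > 0, p < 0.005),
    ``intersection``, ``gestage`` (slope < 0, p < 0.05 in every subset;
    includes the reference cause), ``rare_filtered`` and ``reference``.
    """
    return {
        "reference": {"7980"},
        "profile": {"4275", "4809", "4661"},
        "trend": {"4275", "4809", "7469"},
        "intersection": {"4275", "4809"},
        "gestage": {"7980", "7775"},
        "rare_filtered": {"2770"},
    }
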