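# Methods

## The screening problem

SIDS is a diagnosis of exclusion with two well-known population signatures: a
peak of deaths around the third month of life, and a steep drop in incidence
after the 1994 "Back to Sleep" safe-sleep campaign. The package screens every
cause of death in a linked birth–infant death cohort for these signatures and
for a third, more specific one: a negative regression slope of age at death on
gestational age, i.e. preterm infants dying at *older* postnatal ages, as
expected if mortality risk is anchored to a critical developmental window
measured from conception rather than from birth.

## Code harmonization

U.S. mortality data switch from ICD-9 to ICD-10 coding in 1999, and the
official General Equivalence Mappings (GEM) between the revisions are
many-to-many. The harmonizer treats the codes *observed in the cohort* as
graph nodes, adds an undirected edge for every GEM row (either direction)
whose two codes are both observed, and takes connected components as the
harmonized cause groups. Design choices:

* **Restriction to observed codes.** Building components over the full GEM
  universe would merge groups through bridge codes that never occur in the
  data; restricting first keeps groups as fine as the data allow.
* **GEM flags ignored by default.** Any listed pair counts as an equivalence
  edge; an `edge_filter` predicate on the flag string supports sensitivity
  analyses (e.g. dropping approximate mappings).
* **Deterministic ids.** A group's id is its lexicographically smallest member
  code — stable across runs and platforms; readable aliases are a presentation
  concern kept out of the algorithm.
* Component extraction is delegated to networkx; the test suite cross-checks
  it against a brute-force union-find oracle on hundreds of random instances.

## ETL conventions

* Age week *w* is 0-based and half-open: days [7*w*, 7*w*+7); day 364 is the
  last infant-death day (week 52). The conversion is floor division.
* ICD revision: 9 for years before 1999, 10 from 1999 on.
* Eras: before = 1986–1991, during = 1995–1999, after = 2000–2005; all other
  years (including the missing 1992–1994 archive years) are excluded from era
  analyses.
* **Rare-cause filter.** "More than 20 cases per year" is implemented as a
  strict mean annual count > 20 over the in-scope years (years without deaths
  count as zero). The mean is robust to single sparse years; a stricter
  every-year variant sits behind `per_year=True` for sensitivity checks.
* Rows whose gestation or age fields hold in-band unknown sentinels are
  dropped and counted, never imputed.

## The correlation screens

Profiles are frequency vectors over the full week axis 0–52 (normalized
counts, not raw counts), compared by Pearson correlation with no windowing.
Annual series are percent-of-mean over the in-scope years, so causes with very
different absolute levels are comparable. Thresholds follow the screening
criteria exactly: profile screen inclusive at r ≥ 0.5; trend screen strict
(r > 0 and two-sided p < 0.005). P-values use the exact t-transform of r with
n−2 degrees of freedom; n differs between screens (53 weeks vs the number of
in-scope years) and is reported next to every r. No multiple-testing
correction is applied across causes — the procedure is a per-cause screen,
not a family-wise test.

Numerical choices: a vector compared with itself is assigned r = 1 and p = 0
identically (floating-point round trips would otherwise report
0.9999999999999999); inclusive thresholds are tested with an absolute slack of
1e-12 so that pairs constructed to sit exactly at the boundary are included;
constant vectors (zero variance, correlation undefined) are excluded from a
screen and logged, never silently flagged either way.

## The gestational-age screen

Record-level OLS of age at death (weeks) on gestational age (weeks), per cause
and per subset, with the two-sided slope t-test (n−2 df). A cause passes when
slope < 0 **and** p < 0.05 — note the conjunction halves the nominal type-I
rate to 2.5% under a true zero slope, which the calibration tests verify by
simulation. The fit is on records, not on the per-gestational-week means used
for display (those means, with sample SDs for n ≥ 2, are emitted separately
as the plotting table); a means-weighted WLS variant is available behind
`weight_by_week=True`. Minimum fit size is 3 records spanning 2 distinct
gestational weeks; below that the (cause, subset) pair is reported as unfit
rather than dropped, including causes entirely absent from a subset. The full
gestational-age span enters the fit — no truncation of the preterm range.

Subsets: `all`, the three eras, and the two single-ICD-revision subsets, which
use the full span of years coded in each revision.

## The synthetic generator

The generator emulates the structure the analysis consumes, not the byte
layout of the archive:

* **Quota counts.** Each (cause, year) realizes its configured expected count
  exactly. Deterministic quotas make the rare-cause filter and the trend
  screen sharp in tests (a flat cause is *exactly* constant, hence
  deterministically excluded as degenerate); Poisson sampling would blur both.
* **Age at death.** On the week scale,
  `round(peak + slope·(g − 40) + eps)` with
  `eps ~ N(0, hypot(spread, noise_sd))` — the cause's intrinsic weekly spread
  and the residual gestational-age noise act as independent Gaussian
  components, so their convolution has SD `hypot(spread, noise_sd)`. The week
  is clamped to [0, 52] and converted to a uniform day within the week.
  Clamping can bias slope recovery when planted means sit near the
  boundaries, so calibration experiments place the peak well inside the axis
  (week 20).
* **Gestational age** is drawn per record from a configurable distribution on
  weeks 17–47; the default concentrates mass at 39–40 weeks with a
  late-preterm shoulder and a thin extreme-preterm tail (SD ≈ 2.6 weeks). It
  is a plausible stand-in, not an estimate of the real distribution.
* **GEM tables** are generated from an explicit component specification with
  guaranteed spanning edges and random extra within-component edges; no
  emitted row ever crosses two specified components, and the ground-truth
  partition is returned for oracle tests.
* One seeded stream drives all sampling in a documented order (causes in list
  order, years ascending), so any config is a bit-reproducible fixture.

What the generator does **not** emulate: live-birth denominators, maternal
covariates, sleep-position exposure, coding errors, or the real archive's
byte layouts beyond the pluggable fixed-width spec. Passing tests therefore
show that the pipeline recovers structure of the planted kind at realistic
sizes — not that any particular real-world cause has that structure.

## The demonstration cohort

The bundled demo plants eight causes over the 17 era years: a SIDS-like
reference (peak week 11, declining counts, slope −0.6), two causes passing
both correlation screens (same profile shape, counts exactly half the
reference's so the normalized trends coincide), one profile-only cause
(rising trend), one trend-only cause (late profile peak), one
negative-slope cause placed away from the reference profile (peak week 30),
one cause passing nothing, and one rare cause (10 deaths/year) for the
filter. Null slopes are planted at +0.3 rather than 0 so that "does not pass
the gestational-age screen" is essentially sure rather than a 97.5% event;
profile peaks of non-correlated causes were placed so their analytic profile
correlations with the reference sit far from the 0.5 threshold (≈ −0.6 to
0.0). Expected margins at the planted sample sizes are large (|t| ≳ 5 for
every intended pass, wrong-signed slopes for every intended fail), so the
recovery is stable across seeds.

## Problem sizes

The demo cohort holds 18 875 records; calibration runs use 1 000 null causes
of 500 records and 200 planted-slope causes of 2 000 records — sizes at which
the Monte-Carlo bands in the tests (3 standard errors around the 2.5% null
pass rate; ±0.1 on the mean recovered slope) are tight enough to detect real
calibration defects while single replicates stay inexpensive.

## Known limitations

* ICD-10 (WHO mortality) vs ICD-10-CM dialect differences are handled only by
  string normalization (uppercase, strip periods).
* The trend screen excludes exactly-constant series as degenerate; real data
  essentially never produce them, but heavily quantized synthetic configs can.
* The regression screen reports no confidence bands; the per-week summary
  table carries the inputs for either a mean-response or a prediction band.
* Era definitions, thresholds and the ICD switch year are configurable but
  default to the 1986–2005 U.S. analysis constants; other settings are the
  user's responsibility to justify.
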