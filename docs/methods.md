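# Methods

## Adjudication model

Each participant is classified for a flag *F* against the registry:

- `flagged` — at least one *F*-event in the source dataset;
- `is_case` — at least one registry record of invasive breast cancer with a
  diagnosis date inside the study period (default 2004-07-01..2008-12-31);
  with multiple records, the **earliest** diagnosis date anchors the window;
- `true_positive` — flagged, a case, and at least one event inside the
  flag's adjudication window of the anchor date.

Windows are counted in **calendar months on (year, month, day)**: an event
is within *k* months of diagnosis date *d* when it lies between *d* shifted
by −*k* months (symmetric mode) or *d* itself (forward mode) and *d*
shifted by +*k* months, with end-of-month clamping (Jan 31 + 1 month =
Feb 28). This avoids day-count conventions and makes the rules exactly
reproducible. The published description says only "within three months" /
"within 12 months"; whether an event may precede the registry date is
ambiguous, so the direction is a policy switch defaulting to symmetric
(hospital admissions can precede registry notification). Default windows:
3 months for hospital diagnosis, lumpectomy and mastectomy; 12 months for
radiotherapy and medicine claims. Both are configurable, which is also how
follow-up-period sensitivity analyses are run.

A flagged case whose events all fall outside the window counts **both** as
a false positive (it dilutes PPV) and as a missed case (it dilutes
sensitivity); specificity's denominator is non-cases only. The four counts
therefore reference explicit denominators (`n_flagged`, `n_cases`,
`n_noncases`) rather than a strict 2×2 partition, and raw counts are always
emitted so every displayed percentage re-derives exactly.

### Self-report

The survey records current age in years and months and whole-years age at
diagnosis. The proxy *diagnosis year* is computed purely in calendar
months: birth month = completion month − (years·12 + months); the window
opens at the month of the reported-age birthday and spans exactly 12
months. Day-of-month is ignored throughout, since the survey never captures
it. A self-report is evaluable only against the comparison period
(2004-07..2005-12, the interval over which every participant had uniformly
had the opportunity to report before recruitment began): flagged = reported
and window overlaps the period; case = registry diagnosis inside the
period; true positive = both. Non-reporters and reporters whose window
misses the period fall to the true-negative/false-negative arms.

Inside a combination expression, a self-report leaf contributes its
proxy-window classification while the combination's `is_case` is judged
against the full study period, mirroring the separate treatment of the
standalone self-report row (which keeps comparison-period semantics). The
source description does not state how self-report was time-anchored inside
combinations; this interpretation is isolated behind the policy object.

### Misreported-age audit

Among self-report false positives (window overlaps the period, no registry
record in it), the audit counts those with **any** registry record outside
the comparison period — genuine cases who misstated their age at diagnosis
rather than their history — and reports the proportion (not applicable,
rather than zero, when there are no false positives).

## Code catalog

Flags are defined by versioned code lists shipped as YAML
(`caseflag/data/code_lists.yaml`): ICD-10-AM C50.0–C50.9 for the registry
and hospital principal-diagnosis flags; 4 mastectomy and 10 lumpectomy
ICD-10-AM procedure codes; 4 MBS radiotherapy items; 17 PBS medicine items
(tamoxifen, toremifene, anastrozole, exemestane, letrozole, goserelin,
trastuzumab, lapatinib, and the 500 mg medroxyprogesterone preparation
only, the lower doses being subsidised for other indications — the dose
restriction is therefore enforced by item code, no dose field is needed).
Codes are strings (leading zeros, suffix letters), normalised by trimming,
upper-casing and folding en-/em-dashes to hyphens; normalisation is
idempotent. Only the principal hospital diagnosis triggers the diagnosis
flag. Because it is not documented whether 3-character site codes occur in
hospital data, `code_matches` accepts bare `C50` and undotted `C504`
alongside the dotted forms.

## Synthetic cohort generator

The generator emulates the five linked datasets at desk scale. Study
conditions are defaults: prevalence 0.014, study period 2004-07..2008-12,
comparison period 2004-07..2005-12, recruitment window 2006-01..2009-04,
ages ≥ 45. Each dated flag is an independent event process with a rate
among cases (events at diagnosis date + delay) and among non-cases (events
uniform over the study period). Default rates are calibrated to the
published single-flag operating characteristics via

```
case_rate    = Se
noncase_rate = p·Se·(1−PPV) / (PPV·(1−p))
```

which inverts the PPV/Se definitions when all case events are
window-consistent. Default delays are uniform 0–60 days for the 3-month
flags and 0–300 days for the 12-month flags — inside the adjudication
windows, so calibration targets are exact in expectation. These delay
supports are stated assumptions (the source reports no empirical delay
distributions), chosen as plausible treatment lags. Surgery-only
admissions carry a neutral principal code so the per-flag processes stay
independent; flagged hospital-diagnosis rows carry the participant's
registry site code (cases) or a random C50.x (non-cases).

**Sampling regimes.** With `calibration_mode` on (default), events are
assigned by *fixed-count (quota) sampling*: exactly `round(rate × pool)`
members of each group fire, so realized rates equal configured rates up to
integer rounding and a calibrated cohort reproduces its target row's PPV
and sensitivity essentially exactly (residual error < 0.1 points at the
default scale). With it off, all draws are Bernoulli, which is the honest
stochastic regime for power/robustness exploration. Case status itself is
always Bernoulli(prevalence); calibration helpers therefore compute rates
from the *realized* case counts so recovered PPV does not depend on the
binomial draw.

**Self-report process.** Comparison-period cases report with
`report_prob_case`, stating their true age at diagnosis (optionally
perturbed via `age_misreport_prob`); the window then contains the diagnosis
month, giving a true positive. All other participants falsely report with
`report_prob_noncase`, with a reported age chosen so the window covers a
uniformly drawn month of the comparison period. A configured
`misdated_case_share` of false reporters are genuine cases of another
period: the generator prefers participants who already hold an
out-of-period registry record and mints records (diagnosis uniform over the
study period outside the comparison period) for the remainder, preserving
one registry record per participant. The default share 0.69 matches the
audited value the package's recovery tests target.

**Combination rows.** The correlation structure between flags in real data
is unknown, so a published combination row cannot be recovered from
independent per-flag processes. `generate_combination` instead simulates
the combination as one compound process calibrated with the same algebra:
signal participants receive events for a minimal satisfying leaf set of the
expression (all children of an AND, the first child of an OR), case events
inside each leaf's own window.

**Determinism.** One root seed; per-dataset and per-flag substreams are
derived as `SeedSequence((seed, crc32(label)))`, so adding a dataset or
flag never perturbs the draws of another. Identical configuration and seed
give byte-identical CSV output.

## What the simulations do and do not show

Passing recovery tests show the pipeline — extraction, window logic,
boolean evaluation, proxy-window arithmetic, metric denominators — is
internally correct and can recover known operating characteristics at
realistic prevalence and scale. They do not validate the flags on real
linked data: the generator omits DCIS, death and out-of-state migration,
repeat primaries, hospital transfers, correlated flag processes and any
secular change in coding or practice. Published-row defaults describe one
cohort of consenting women aged 45+ and need not transport elsewhere.

## Numerical and design choices

- Problem sizes: recovery runs use n = 50,000 at prevalence 0.014 (≈ 700
  cases, ≈ 230 in the comparison period), a desk-scale stand-in for the
  original cohort of 143,010 chosen to keep the whole suite fast while
  leaving quota-sampling rounding error far below reporting precision.
- Percentages are displayed half-up to one decimal; underlying proportions
  and raw counts are always available.
- Exact Clopper–Pearson 95% intervals accompany every metric (an extension;
  the published tables print percentages only).
- Undefined metrics (zero denominator) are reported as not-applicable,
  never 0.
- Expression grammar: AND binds tighter than OR, parentheses override; all
  published rows are parenthesized where it matters, so precedence never
  changes a published result (verified by test).
- An admission listing both lumpectomy and mastectomy codes yields both
  flags; they are separate flags combinable by OR.
- Degenerate inputs: empty cohorts are an error for metrics; AND/OR over an
  empty child set is an error, not vacuous truth; events referencing
  unknown participants abort as linkage violations.

## Known limitations

- The compound-process calibration pins a combination's PPV/Se but not the
  joint distribution of its leaves; per-leaf marginals in such runs are not
  themselves calibrated.
- Minted out-of-period registry records for misdated self-reporters are not
  accompanied by synthetic treatment events, so a full-default cohort
  slightly under-flags its out-of-period cases in the dated-flag processes.
- Month-interval logic assumes Gregorian calendar dates throughout; no
  support for partial or imputed dates.
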