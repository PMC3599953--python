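# caseflag

Validation of coded case-ascertainment **flags** for invasive breast cancer
against a cancer-registry gold standard, with a synthetic linked-cohort
generator for desk-scale testing and calibrated parameter recovery.

## The problem

Statutory cancer registries are the gold standard for identifying cancer
cases, but researchers often hold only administrative or self-reported data
— hospital separations, outpatient medical-service claims, prescription
dispensings, a baseline survey — without registry linkage. A *flag* is a
coded signal in one of those datasets used to identify a suspected case: a
principal inpatient diagnosis of invasive breast cancer (ICD-10-AM
C50.0–C50.9), a lumpectomy or mastectomy procedure code, a breast
radiotherapy claim (MBS items 15221, 15236, 15251, 15266), a dispensing of
a breast-cancer-specific medicine (17 PBS items), or a self-reported
doctor-diagnosed breast cancer. `caseflag` implements the validation of
such flags — alone and in AND/OR combinations — against registry records,
for the setting of a cohort of women aged 45 and over observed over a study
period of July 2004 to December 2008.

## The method

For a flag *F* with adjudication window *w* (3 calendar months for hospital
diagnosis and surgeries, 12 for radiotherapy and medicines), a participant
with registry diagnosis date *d* and at least one *F*-event at date *t* is a
**true positive** iff |*t* − *d*| ≤ *w* months (symmetric by default;
forward-only is a policy switch). Writing `flagged` for having any
*F*-event and `case` for having a registry record in the study period,

- **PPV** = TP / #flagged,
- **sensitivity (Se)** = TP / #cases,
- **specificity (Sp)** = TN / #non-cases, with TN = neither flagged nor a case.

A flagged case with no in-window event counts against both PPV and
sensitivity. Self-reports are handled differently: the survey gives age in
years and months at recruitment and whole-years age at diagnosis, from
which a 12-calendar-month proxy *diagnosis year* is derived (e.g. recruited
August 2008 aged 72y 4m, diagnosis reported at 68 → April 2004–March 2005).
A self-report is a true positive when that window overlaps the comparison
period (July 2004–December 2005, over which all participants had uniformly
had the chance to report) *and* a registry diagnosis falls inside the
period. Combinations such as `(lumpectomy OR mastectomy) AND diagnosis`
are boolean trees over flags, flagged by presence and true-positive only
when the tree holds over per-leaf window-consistent indicators.

Because the real linked data are confidential, the package ships a
synthetic generator that emulates the five dataset schemas with the
statistical structure the analysis assumes (~1.4% case prevalence,
per-flag event rates among cases and non-cases, treatment delays relative
to diagnosis, age-at-diagnosis misreporting). `calibrate_to_row` inverts
the PPV/Se definitions so a generated cohort reproduces any published
validity row, enabling end-to-end parameter-recovery tests.

## Worked example

```python
from caseflag import GeneratorConfig, build_report, generate, select_flags
from caseflag.tables import INDIVIDUAL_DATASET_ROWS

cohort = generate(GeneratorConfig(n_participants=20_000, seed=7))
report = build_report([r.expression for r in INDIVIDUAL_DATASET_ROWS], cohort,
                      labels=[r.label for r in INDIVIDUAL_DATASET_ROWS])
best = select_flags(report, ppv_floor=0.85).iloc[0]
print(best["label"], best["ppv_pct"], best["sensitivity_pct"])
```

prints (cohort of 20,000 with 275 registry cases):

```
Diagnosis of invasive breast cancer 85.6 86.2
```

i.e. among women flagged by a principal hospital diagnosis of invasive
breast cancer, 85.6% are registry cases with an in-window admission, and
the flag finds 86.2% of all registry cases — the flag with the greatest
sensitivity among those meeting the PPV ≥ 85% selection rule. The
`examples/` directory holds short narrative scripts for each capability:
proxy windows, single-flag validity, combination recovery and the
misreported-age audit.

A thin CLI wraps the same library calls:

```bash
caseflag generate --out data/ --seed 3
caseflag evaluate --data data/ --out report.csv
caseflag audit --data data/
```

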