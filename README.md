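# pregrisk

Phenotyping and validation of **women at risk of pregnancy not using any
contraception** in THIN-style primary-care databases.

UK primary-care databases such as THIN (The Health Improvement Network)
record diagnoses as Read codes and prescriptions through a Gemscript-style
drug dictionary. A woman of childbearing age is *at risk of pregnancy* when
her record carries no evidence of contraception, infertility, menopause or
current pregnancy. `pregrisk` implements a codelist-based algorithm that
builds such a cohort, together with the two-step validation analysis
(record review and practitioner questionnaires) that quantifies how often
the algorithm is right — exercised end to end on synthetic data with planted
ground truth, because the real databases are access-restricted.

This is a tool for pharmacoepidemiologists who build and validate EHR
phenotypes: the cohort algorithm, the validation statistics and the
synthetic-data generator are all first-class, tested library code.

## The algorithm

Eligibility: female, aged 15–45 at enrolment start (age = enrolment year −
birth year; the registry stores year of birth only), permanently registered,
and at least one year with the practice. An eligible woman is then
**excluded** if any code from an exclusion-category codelist falls inside
that category's lookback window (all windows end at enrolment end, bounds
inclusive):

| category | lookback |
|---|---|
| infertility, iatrogenic infertility | lifetime |
| menopause | lifetime |
| partner vasectomy | lifetime |
| prescribed contraception | 12 calendar months |
| Cu-IUD / LNG-IUS (LARC) | 60 calendar months |
| progestogen-only implant (LARC) | 36 calendar months |
| non-prescribed contraception | 12 calendar months |
| pregnancy | 6 calendar months |

A woman free of every criterion is classified at risk. The package also
replays a *two-pass codelist correction*: classify with a deficient search
list v1, discover the missing drug codes, re-classify with v2 ⊇ v1 and
report every reclassified woman (monotone by construction).

Validation estimates the positive predictive value

PPV = confirmed by gold standard / classified at risk by the algorithm,

with Wilson score and exact (Clopper–Pearson) 95% intervals, under two
handlings of "unknown" questionnaire answers (count as non-case, or exclude
from both numerator and denominator), plus the cross-link of the two gold
standards (percentage agreement, NPV).

## Worked example

```sh
pregrisk run --seed 1 --out run/
```

generates 5,000 women, classifies them under the deficient and the corrected
codelist, draws the stratified validation sample (25 per age band: 18–20,
20–25, 25–30, 30–35, 35–40, 40–45), simulates both gold standards and
prints, among other lines:

```
[v1] screened: 5000
  ineligible: 0
  excluded (>=1 criterion): 1572
  at risk of pregnancy: 3428
codelist correction: 175 of 3428 v1 at-risk women reclassified (5.1%)
validation sample: 150 women, free text in 9
ppv_record_review: 98.7% (95% CI: 95.3–99.8) [148/150, clopper_pearson]
ppv_questionnaire_enrolment_as_noncase: 36.0% (95% CI: 28.3–44.2) [54/150, clopper_pearson]
ppv_questionnaire_enrolment_excluded: 94.7% (95% CI: 85.4–98.9) [54/57, clopper_pearson]
questionnaire_response_rate: 91.3% (95% CI: 85.6–95.3) [137/150, clopper_pearson]
```

Reading these numbers: the screened population loses 1,572 women to at
least one exclusion criterion; correcting the drug-code list removes a
further 175 of the 3,428 provisional at-risk women. Record review (which
sees the planted truth) confirms 148 of the 150 sampled — the 2 misses are
women whose contraception was never coded. The questionnaire PPV swings
from 36.0% to 94.7% depending on whether the many "unknown" practitioner
answers count as refutations or are dropped — which is exactly why unknown
handling is an explicit, never-defaulted parameter. Every printed number is
re-derivable from the CSVs in `run/`, and `run/manifest.json` records seeds
and file digests; re-running the same configuration reproduces the digests
byte for byte.

The same operations are available as a library:

```python
from pregrisk import make_estimate, crosslink_from_counts, UnknownHandling

make_estimate(122, 123, ci_method="wilson").percent        # 99.2
crosslink_from_counts(33, 48, 0, 1, UnknownHandling.AS_NONCASE).ppv.percent  # 40.7
```

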