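# Methods

## The phenotype and its observation model

The package separates three layers that EHR validation studies usually
conflate:

1. **Truth** — whether a woman genuinely carries an exclusion condition
   (contraception, infertility, menopause, recent pregnancy). In the
   synthetic generator this is planted per woman and per category at
   generation time (`GroundTruth`), so it is exact.
2. **The database** — the coded trace of that truth. Contraception may be
   obtained outside the practice and never coded; the generator models this
   as a per-(woman, category) Bernoulli censoring with probability
   `unrecorded_contraception_rate`, applied only to contraception
   categories. Infertility, menopause and pregnancy are assumed always
   coded.
3. **The gold standards** — record review observes truth directly (the
   reviewer reads the whole record); the practitioner questionnaire
   observes truth through a per-item response model with "unknown"/empty
   rates and a recall-error flip for retrospective items.

The algorithm only ever sees layer 2, which is why its PPV against layer 1
is below 100% exactly when censoring is on, and 100% when it is off
(perfect-recording recovery — asserted for all 50,000 women in the
acceptance suite).

## Eligibility and windows

Eligibility: female, permanent registration, `enrolment_start −
registration_date ≥ 365` days, and age within [15, 45] inclusive, where age
is enrolment-start year minus birth year — the source databases store year
of birth only for adults, so finer age arithmetic would be spurious
precision. A registration date after the enrolment period yields a negative
duration and is an ordinary ineligibility, not an error.

Lookback windows are calendar-month arithmetic anchored at enrolment start
(six months before 2016-09-01 is 2016-03-01, via `dateutil.relativedelta`),
with **both bounds inclusive** and every window extended through enrolment
end: an exclusion event during the enrolment period disqualifies too, so
the classification is cross-sectional over the whole window. Lifetime
lookbacks are floored at 1900-01-01. The menopause window is lifetime by
default (menopause is absorbing) but configurable like every other window.
LARC handling is purely window-based — an insertion code within the
device's natural life cycle (60 months Cu-IUD/LNG-IUS, 36 months implant)
excludes; no device-removal or duration modelling is attempted. This
reproduces the algorithm's one known blind spot, exercised in the tests: an
implant inserted slightly more than 36 months before enrolment is invisible
and the woman is (wrongly) classified at risk.

Ineligible women are never tested for exclusions, keeping the attrition
funnel's three buckets (ineligible / excluded / at risk) disjoint;
`AttritionReport` enforces the identity `screened = ineligible + excluded +
at_risk` as a dataclass invariant, with a woman counted once in `excluded`
however many criteria she meets (the per-category tallies may overlap).

## Synthetic generator defaults

Defaults anchored to observable rates: free-text availability 6.5% of
records; per-item questionnaire "unknown" rates 51.6% (contraception at
enrolment), 46.9% (contraception now), 54.7% (ever use), 21.1% (pregnant),
75.8% / 75.0% (intention items); response rate 133/150 with 5/133 blank
forms.

Free parameters, chosen once as plausible for a childbearing-age
primary-care population and not revisited: per-category prevalences
(prescribed contraception 0.18, Cu-IUD/LNG-IUS 0.05, implant 0.03,
non-prescribed contraception 0.05, partner vasectomy 0.02, infertility
0.02, iatrogenic infertility 0.005, menopause 0.03, pregnancy 0.06), which
jointly exclude roughly a third of eligible women; under-recording 0.1;
recall error 0.05 on retrospective items; uniform ages 15–45. Event dates
are uniform over each category's own lookback window (lifetime draws capped
at ten years), so every *recorded* true hit is visible to the algorithm by
construction; tests that probe window boundaries override the per-category
timing range to plant events just outside.

What the generator does **not** emulate: clinical coding depth
(comorbidities, consultations), regional or practice-level clustering,
age-dependent prevalences, device removals, or pregnancy outcomes. Passing
tests therefore demonstrate the algorithm's and estimators' correctness
under the stated observation model, not the external validity of any
particular prevalence.

With censoring drawn per (woman, category), the expected PPV of the
algorithm against truth has the closed form
P(at risk) / (P(at risk) + q · P(contracepting))
when a single contraception category is active (with several categories a
woman needs every category censored, so the formula is a lower bound on
censoring). The acceptance suite checks the single-category form against a
50,000-woman Monte-Carlo run within three binomial standard errors.

## Validation statistics

PPV is confirmed-by-gold over classified-at-risk. "Unknown" gold verdicts
change conclusions, so the handling is a required parameter with two
definitions: `as_noncase` keeps unknowns in the denominator as refutations
(conservative); `excluded` drops them from numerator and denominator
(complete-case). PPV with an all-unknown gold standard raises under
`excluded` and returns 0 under `as_noncase`.

Both binomial interval methods ship because published validation studies
print either, sometimes both within one paper: the Wilson score interval
(inverted score test) and the exact Clopper–Pearson interval (beta
quantiles, with low = 0 at zero successes and high = 1 at n successes).
They are computed via `statsmodels.stats.proportion.proportion_confint`;
the test suite verifies both against an independent vectorized bisection on
the defining equations — the score-test quadratic for Wilson, the tail
coverage equations for Clopper–Pearson — to 1e-9 for every x ≤ n ≤ 200,
and checks the exact interval's empirical coverage ≥ 95% at n = 30 over
20,000 replicates. The default method for reports is Clopper–Pearson.

Cross-linking treats the questionnaire as the gold axis of a 2×2 table
against record review; PPV = confirmed-by-both / confirmed-by-index, NPV
analogously on the non-confirmed row (undefined, and reported as absent,
when the index confirms everyone), percentage agreement = diagonal / total.
Women unknown to the index contribute no information and are dropped; gold
unknowns follow the chosen handling. The table constructor accepts raw 2×2
counts directly, so published tables can be re-analysed without per-woman
data.

Stratified sampling allocates an equal number (default 25) per age band
with bands half-open [low, high) and the final band closed at 45 — the
conventional shared-endpoint listing 18–20, 20–25, …, 40–45 partitions
cleanly under this rule. The default bands start at 18 although the cohort
starts at 15, mirroring common validation practice of sampling adults; the
plan is fully configurable. A band with too few candidates is an error
naming the band unless short bands are explicitly allowed.

All percentages are reported to one decimal with round-half-even, and every
rendered percentage equals `round(100·numerator/denominator, 1)` — the
tabulator will print 96.2% for 128/133 valid questionnaires even where a
source table might show a discrepant figure, because rendered numbers are
always recomputed from their counts.

## Pipeline and determinism

`run_pipeline` chains generate → classify under v1 → codelist-correction
replay → classify under v2 → stratified sample → gold-standard simulation →
estimates → tabulation. Per-stage seeds are derived from the global seed by
SHA-256 of the stage name (kept below 2³¹), so inserting a stage does not
shift earlier random streams. Every intermediate table is written as CSV;
the manifest records stage seeds, codelist versions, withheld codes and a
SHA-256 digest per output file, and re-running a configuration reproduces
identical manifests. Any stage failure aborts with the stage name.

## Problem sizes used by the test suite

Desk-scale statistics are exact and instant. The property checks run at:
50,000 women for perfect-recording recovery and for the Monte-Carlo PPV
comparison; 5,000 women for codelist-growth monotonicity; 2,500–3,000 for
end-to-end determinism; 300–400 for triple-loop oracle equivalence; 200
replicates × 128 questionnaires for response-model calibration. These sizes
give comfortable statistical resolution (e.g. three standard errors on the
PPV check is ±0.4 percentage points) while keeping the whole suite around
ten seconds.

## Known limitations

- Under-recording applies uniformly across contraception categories; real
  censoring is method-specific (LARC insertions are better coded than
  condom advice).
- The questionnaire model draws items independently given truth; real
  practitioner responses are correlated within a form.
- No follow-up: the package classifies a cross-section and validates it; it
  does not model subsequent pregnancies or outcomes.
- The eligibility screen cannot distinguish "aged 15 at enrolment but 14 at
  an event date"; events are windowed on dates only, with no age-at-event
  handling.
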