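# Methods

This note documents the analytic model implemented by `rxlines`, the
choices made where dispensing data underdetermine the analysis, the
synthetic-claims generator used for validation, and known limitations.

## Data model

Dispensing claims carry no exposure duration, diagnosis or prescribed dose:
only the fact that a medicine was supplied on a date. Exposure is therefore
projected from each dispensing as `[dispense_date, dispense_date +
days_supply)`, with `days_supply` taken from the classification table
(default 30 days per oral pack, 28 days per depot injection — standard pack
sizes and injection intervals; editable per entry). Quantities above one
pack are deliberately ignored when projecting exposure: stockpiling
behaviour cannot be distinguished from split supply, and extending exposure
by quantity would mechanically suppress gap detection. Dates are ISO-8601;
all interval arithmetic is in integer days; months are reported as
days / 30.44.

Patient age is derived from year of birth only (index year − birth year),
the finest resolution the data model carries; patients aged exactly the
minimum (16) at index are included.

## Cohort (new-user design)

Inclusion requires a first antipsychotic dispensing inside the sampling
window, an antipsychotic-free lookback clean period, no antidepressant
dispensing on or before the index date, and minimum age at index. Every
excluded patient receives one primary reason, the first failing rule in the
fixed order: no qualifying dispensing in the window → prior antipsychotic →
prior/concomitant antidepressant → under age. Antidepressants *started
after* index are not exclusions; they trigger line progression as add-ons.
All window dates, the lookback start, the age floor, the 183-day gap, the
90-day polypharmacy threshold and the 365-day comparison horizon live in
one configuration object and are echoed into every run manifest.

## Lines of therapy

The central ambiguity in claims-based line construction is telling a
*switch* from *concurrent therapy* when a new antipsychotic class appears
while the old class's last supply is still nominally active. `rxlines`
resolves it with a look-ahead: the anchor class "continues" past the new
class's first fill if the anchor's next dispensing on or after that date
arrives within its own days-supply plus a 14-day grace (absorbing refill
jitter). If it continues, the new class is a concurrent add-on — the line
number advances but the anchor class is retained and the new class is
recorded in `addon_classes`; if it does not, the transition is a switch and
the new class anchors the next line. Consequences:

* a dispensing gap alone never advances the line (gaps produce
  discontinuation events in the persistence layer, and a same-class refill
  after even a qualifying gap extends the same episode);
* two classes starting the same day are broken deterministically: the class
  earlier in the reporting order (oral atypical, typical LAT, oral typical,
  atypical LAT, clozapine) anchors line 1 and the other becomes a same-day
  add-on opening line 2;
* adjunct dispensings on or before the first line's start are baseline
  add-ons (recorded, no progression); the first dispensing of each adjunct
  class strictly after the line start advances the line once.

## Persistence (gap method)

Per episode, persistence runs from the episode's first dispensing to the
first of: (a) the start of a later episode with a different class
(switch); (b) the last antipsychotic dispensing of any class followed by at
least `gap_days` = 183 days (≈ 6 months) with no antipsychotic dispensing —
the discontinuation is dated at that last dispensing, not at supply
exhaustion; (c) censoring at the last dispensing when the remaining window
is shorter than the gap. Both switch and discontinuation count as events in
the survival analysis; only administrative censoring is a non-event.

**Follow-up capping.** A discontinuation occurring within the last
`gap_days` of the window can never be ascertained — its six-month silence
would run past the end of data. Left uncapped, such subjects are censored
exactly at their (unconfirmed) event times, which is informative censoring
and inflates the product-limit curve (≈ +15% on the median in simulation).
Survival analyses therefore cap each subject's follow-up at
`window_end − gap_days` after episode start (`pipeline.class_km`); within
that boundary both event types are fully observable and censoring is purely
administrative. The persistence *records* keep the uncapped convention so
the raw event dates remain inspectable.

Time to retreatment runs from the discontinuation date to the next
antipsychotic dispensing (necessarily > `gap_days` later), censored at the
window end; return-to-treatment classes (same class / different class / no
return) use the class of that first post-gap dispensing.

## Survival statistics

Kaplan–Meier, Greenwood variance, the two-group log-rank test and the
fixed-horizon risk ratio are implemented directly on numpy (the library
versions exist only in the test suite as independent oracles). Conventions:
at tied times events precede censorings, so subjects censored at *t* remain
in the risk set at *t*; the median is the smallest observed event time with
S(t) ≤ 0.5 and is reported as undefined when the curve never reaches 0.5
(heavy censoring — the clozapine pattern); the log-rank variance uses the
hypergeometric form with the n = 1 term dropped. The class comparison is
the ratio of KM-estimated cumulative discontinuation risks at 365 days,
with the 95% CI built on log RR via the delta method from the Greenwood
variances (Katz). A ratio below one means lower discontinuation risk than
the reference (oral atypicals). The p-value reported alongside comes from
the log-rank test over full follow-up; the CI and the p-value answer
slightly different questions and are both emitted. A proportional-hazards
model was deliberately not used: the quantity compared is a fixed-horizon
risk, not a hazard.

## Switching matrices and descriptive tables

Switch cells condition on *continuous* therapy: only first-line persistence
records whose event is a switch count, so a different class started after a
qualifying gap is a retreatment, never a switch. All horizons in one call
share a single denominator — first-line starters with at least
max(horizon) days of potential follow-up — which makes cells cumulative in
the horizon by construction (a per-horizon denominator would admit late
starters at 6 months that the 12-month column drops, breaking
cumulativity). Share tables use treatment-episode denominators (a patient
with several lines contributes once per line); stratified shares support
calendar year of episode start, decennial age bands from 16 (16–24, …,
85+) and sex. Polypharmacy counts days covered by ≥ 2 qualifying classes
(two antipsychotic classes, or one antipsychotic class plus an adjunct)
via an interval sweep, flagging at ≥ 90 days; the regimen census counts
distinct antipsychotic classes covering a census date per patient.

## Synthetic-claims generator

The generator emulates the structure of subsidised-dispensing claims with
known per-patient ground truth. Study-like defaults
(`study_like_config()`): class shares 62/19/9/7/3% (oral atypical, typical
LAT, oral typical, atypical LAT, clozapine); exponential persistence with
medians 240/268/189/387 days and clozapine set to ~60 months so its median
lies beyond follow-up; eventual-switch probabilities concentrated on the
typical-oral → typical-LAT route with no switching out of clozapine; 53% of
discontinuers retreat after a 183-day floor plus an exponential tail with
overall median ≈ 10 months, 70% on the same class; adjunct add-on rates
22/8/4% (antidepressant/antiepileptic/lithium); 10% concurrent dual
therapy; exclusion-triggering patients at 10/10/2%
(prior antipsychotic / prior antidepressant / under age); 61% male; an age
distribution with ~55% under 55; refill cadence 30 days oral / 28 days
depot with ±3-day uniform jitter. These parameters qualitatively mirror
the real-world prescribing setting the package targets; they are
illustrative, not a reproduction of any licensed dataset.

Design points that matter for validation:

* each patient's first-line event day E1 is drawn from the class's
  configured distribution; with the row-sum of the switch matrix it becomes
  a switch (destination drawn from the row), else a discontinuation. The
  generator places the final fill exactly on the event day — the same
  dating the gap method recovers — so measured durations equal the drawn
  event days and estimator checks are exact, not approximate;
* censoring arises only from the window end, matching administrative
  censoring, and is never injected separately;
* the emitted ground-truth table records every stochastic choice (label,
  first class, event type and day, switch destination, retreatment day and
  class, add-ons, regimen size at the census), so cohort tallies, class
  shares, KM medians and switch cells can be compared against truth.

What the generator does **not** model: dose changes, within-class molecule
switching, seasonality, regional variation, pricing/concession dynamics,
multi-step switch chains, or informative censoring (e.g. death). Passing
recovery tests therefore demonstrates that the pipeline measures what the
generative model encodes — not that real claims obey that model.

## Validation sizes and numerical choices

The test suite validates against: hand-traced patient histories (exact
episode/event/date equality); lifelines as an independent oracle for the
product-limit curve and log-rank statistic (agreement to 1e-10 on 100
random fixtures); log-rank type-I error calibration under equal exponential
hazards (200 per arm, 1,000 replicates, rejection rate within [0.03,
0.07]); Katz-interval coverage for a true 12-month risk ratio of 0.5 (300
per arm, 500 replicates, coverage within [0.93, 0.97]); a brute-force
per-day polypharmacy counter on 200 random fixtures including the
89/90-day boundary; and parameter recovery on a 5,000-patient study-like
cohort (exclusion tallies exact; first-line shares within 3 binomial SE;
switch cells within 3 SE; KM medians within 5% of configured values).
These sizes keep the full suite within a few minutes on one CPU while
leaving the binomial tolerances meaningful.

One caveat on the 5% median-recovery band: under the study-like shares the
atypical-LAT class receives ~7% of 5,000 patients, and the sampling SE of
a KM median at that size (with administrative censoring) is ~8% — wider
than the band. The pipeline itself is exact (its KM medians coincide with
the ideal estimate computed from the generator's own ground truth), so an
out-of-band result for that class reflects the luck of the preregistered
seed, not an implementation error; the seed is fixed and is not re-chosen
on failure.

## Limitations

The classification table keys on molecule + formulation, not on national
item codes, so claims extracts must normalise molecule names. Exposure
days-supply is an assumption, not an observation. Reasons for
discontinuation are unobservable in claims. The add-on rule advances the
line at the first adjunct fill regardless of indication, so adjuncts
prescribed for unrelated conditions still progress the line — an inherent
over-count shared by any claims-only line algorithm.
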