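# Methods

This note documents the statistical procedures `edspc` implements, the
modelling assumptions behind the synthetic data generator, and the
choices made where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Study design being modelled

An interrupted time series over four contiguous phases — a baseline
year (2014-07-01 to 2015-06-30) and three PDSA improvement cycles
starting 2015-07-01, 2015-12-01 and 2016-07-01 (through 2017-06-30) —
in an ED seeing roughly 90,000 patients a year. Two processes are
monitored: how often a peripheral blood culture is ordered (BCOR), and
how often an ordered culture grows a contaminant (BCCR). Phases are
*given*, not discovered: the package performs no change-point search.

## Record model and exclusions

Visits and cultures are plain CSV tables validated row by row;
malformed rows (unparseable timestamps, departure before arrival, a
culture outside its visit window, growth/organism inconsistencies,
duplicate ids, unknown visit links) land in a rejects report with a
reason rather than being dropped silently. Exclusion is record-level:
a culture carries zero or more flags (central line, VP shunt, oncologic
condition, neutropenia, transplant history) attached at order time, and
any flag removes it from every downstream measure. Filtering is
idempotent and order-deterministic (time, then culture id).

Organism classification is a data table, not an algorithm. The shipped
default follows the conventional pediatric blood-culture groupings —
coagulase-negative staphylococci, *Micrococcus*, *Bacillus* (other
than *B. anthracis*), diphtheroids/*Corynebacterium*,
*Cutibacterium*/*Propionibacterium* and viridans-group streptococci as
contaminants; *S. aureus*, *S. pneumoniae*, group A/B streptococci,
enteric gram-negatives, *N. meningitidis*, *H. influenzae*,
enterococci, *P. aeruginosa* and *Candida* as pathogens — and any
study should replace it with its own two-column CSV where its
conventions differ (viridans streptococci in particular are
context-dependent). Lookups are case- and whitespace-insensitive; an
unknown label is a hard error listing the offending labels, because a
silent default would corrupt both the contamination rate and the
missed-bacteremia measure. Polymicrobial results are out of scope: one
organism label per culture.

## T chart

The T chart plots the time between consecutive contaminant events.
Gaps from an in-control rare-event process are heavily right-skewed
(approximately exponential/Weibull), so each gap *t* (fractional days)
is transformed to

    y = t^(1/3.6)

before charting, the standard power transformation for
time-between-events charts, which renders the distribution near enough
to symmetric for individuals-chart limits. Limits per phase are the
individuals/moving-range construction:

    center = mean(y_i),   sigma = mean(|y_i − y_{i−1}|) / 1.128

with zones at ±1σ, ±2σ, ±3σ. Display values are back-transformed
(t = y^3.6), giving the clinically readable "one contaminant every
k days" center line; the back-transformed lower bound is clipped at 0.
For exponential gaps of mean m the back-transformed center converges
to m·Γ(1+1/3.6)^3.6 ≈ 0.69 m, not to m — the chart centers the
*transformed* mean — and the acceptance suite checks this closed form
by simulation.

Conventions the construction needs but the design left open, fixed
here deterministically:

* the first gap is measured from the monitoring start
  (``first_gap="from_start"``; ``"drop"`` is available);
* duplicate event timestamps are an upstream error, never silently
  merged;
* a phase with fewer than two events gets no limits (points are still
  plotted) rather than extrapolated ones.

## Special-cause rules

Five Western-Electric/Nelson-style rules on the transformed scale:

| rule | window |
|---|---|
| `outside_3sd` | 1 point beyond ±3σ |
| `four_of_five_1sd` | ≥4 of 5 consecutive beyond 1σ, same side |
| `two_of_three_2sd` | ≥2 of 3 consecutive beyond 2σ, same side |
| `eight_same_side` | ≥8 consecutive on one side of center |
| `six_trending` | ≥6 consecutive strictly increasing/decreasing |

Tie-breaks are explicit: a point exactly on a zone boundary is inside
the zone (all "beyond" comparisons strict); a point exactly on the
center line belongs to neither side; an equal consecutive pair resets
a trend run. Overlapping qualifying windows for the same rule and
direction merge into one signal whose indices are the beyond-zone
points of the merged span. The engine is verified against an
independent brute-force window-enumeration oracle — exhaustively over
all short series on zone-straddling value alphabets and by sampling on
longer random series, including per-point sigma (P-chart geometry).

### Phase structure and limit freezing

Display limits are always recomputed from each phase's own points.
Detection policy is separate: under the default ``freeze_prior``, each
post-baseline phase is tested against the *previous* phase's frozen
limits — the interrupted-time-series question "did this cycle move the
process off its previous behaviour?" — while the first phase is tested
against itself (process stability). ``recompute_only`` tests every
phase against its own limits. If a prior phase has no usable limits the
nearest earlier phase with limits is used.

## P chart

Visits are grouped by phase × calendar period (monthly by default,
weekly available; the design's subgroup granularity was not fixed, so
it is a parameter). The subgroup numerator is the number of visits
with at least one included culture — the charted quantity is
"proportion of patients with a culture ordered", which also guarantees
numerator ≤ denominator for multi-culture visits. The phase center is
the pooled proportion Σx/Σn (hence invariant to period granularity);
per-point sigma is √(p̄(1−p̄)/nᵢ), so limits widen as subgroups
shrink, and bounds are clipped to [0, 1]. The default rule set is the
single beyond-3σ rule, judged against the prior phase's pooled center
under ``freeze_prior``. BCOR as a *measure* stays defined as included
cultures / visits.

## QI measures

* **BCCR** per phase: contaminant outcomes / included cultures ordered
  in the phase. **BCOR**: included cultures / ED visits. Both raise on
  empty denominators rather than returning NaN. The closure identity
  BCCR × BCOR × visits = contaminant count holds exactly on any
  dataset and is property-tested.
* **Relative decrease**: 100·(baseline − current)/baseline, reported
  to the nearest integer percent in rendered output (rates print at
  two decimals, CI bounds at one — the conventional precisions).
* **Balancing measure**: per patient, a pair (visit 1, visit 2)
  qualifies when visit 1 ended in discharge with no culture, visit 2
  arrived within 48 h of that departure, and visit 2 had a culture.
  The numerator counts pairs whose return culture grew a pathogen.
  Pairs split into pre/post periods by the return visit's arrival
  relative to the final phase start; the comparison is a Wald
  two-proportion interval. Exclusion flags do not apply here — a
  missed bacteremia is a harm regardless of the patient's device or
  oncologic status. A patient may contribute several pairs; each
  counts once. With a zero denominator in either period the comparison
  is reported as unavailable, never as zero.
* **Two-proportion CI**: Wald, no continuity correction,
  z = Φ⁻¹(0.975) ≈ 1.959964. This is fixed as the default because it
  exactly reproduces the conventional printed intervals at these count
  scales; `alpha` is a parameter.
* **Financial measure**: expected final-phase contaminants = patients
  in the final phase × baseline BCOR × baseline BCCR; averted =
  expected − observed; savings = averted × per-contaminant charge
  (default $3,166, already inflation-adjusted — the package performs
  no inflation arithmetic). The raw (unrounded) expectation is
  reported alongside its rounded value, and an explicit expected count
  can be supplied instead, because a rate-product expectation and a
  directly counted expectation legitimately differ and the report
  should expose, not hide, that gap.

## Synthetic data generator

The generator emulates the statistical structure the analysis
consumes, at the documented study scale:

| parameter | default | meaning |
|---|---|---|
| `daily_visits` | 90000/365 ≈ 246.6 | homogeneous Poisson arrival rate (visits/day) |
| `order_prob` | 4.80, 4.26, 3.82, 3.49 % | per-phase P(culture ordered per visit) |
| `contam_prob` | 3.02, 2.30, 1.58, 1.17 % | per-phase P(contaminant per culture) |
| `pathogen_prob` | 2 % | P(true pathogen per culture), constant |
| `exclusion_prob` | 5 % | P(record-level exclusion flag) |
| `return_visit_prob` | 0.2 % | P(48-h return for a discharged, uncultured visit) |
| `return_culture_prob` | 35 % | P(the return visit gets a culture) |
| `return_pathogen_prob` | 3.6 / 2.3 % | P(return culture is pathogenic), pre/post final phase |
| `los_hours` | U(1, 6) | ED length of stay |

`return_culture_prob` is calibrated so qualifying balancing-measure
pairs accrue at roughly 50/year at the default scale — the order of
magnitude at which a 48-hour return-visit measure is clinically
interesting — and a return culture that is not pathogenic is
contaminated with its phase's `contam_prob`, which keeps the BCCR
estimator unbiased by construction. Return cultures are forced rather
than drawn at `order_prob`, so realized BCOR sits ≈ 0.05 percentage
points above `order_prob` at defaults; recovery tests allow for
exactly this designed excess. Return visits whose stay would cross the
plan end are not generated, keeping every event inside the plan span.

One `numpy` Generator with a fixed draw order drives everything, so a
seed reproduces the CSV outputs byte for byte. The truth file records
the configuration and per-phase realized counts using the same
definitions as the analyzer, and the suite asserts exact agreement
between the two.

What the generator deliberately does **not** model — and therefore
what passing tests do not demonstrate about real data: diurnal or
seasonal arrival structure, phlebotomist- or team-level clustering of
contamination (contamination is i.i.d. per culture), gradual
within-phase drift (rates step at phase boundaries), polymicrobial
growth, antibiotic pretreatment effects, and patients re-appearing
beyond the single scripted 48-hour return. Real charts will show
autocorrelation and overdispersion this generator cannot produce.

## Numerical and reporting choices

* Timestamps are timezone-naive local time at microsecond precision;
  calendar-day granularity is all the analysis interprets.
* Phase intervals are [start 00:00, end + 1 day) — inclusive calendar
  end dates.
* `report.json` is deterministic (sorted keys, no wall-clock content);
  run timestamps and file digests live in `manifest.json` only.
* Problem sizes used by the checks: the rule-engine oracle runs
  exhaustively over all series of length ≤ 6 on a five-level alphabet
  and lengths 8–9 on a three-level alphabet, plus 500 random
  length-30 series; the closed-form center-line check uses 10,000
  simulated gaps; parameter recovery runs the full three-year default
  stream and a 100-seed planted-changepoint power experiment; the
  acceptance script averages 20 one-year baseline streams.

## Known limitations

* The organism table is a convention, not a clinical ruling;
  context-dependent organisms (viridans streptococci in endocarditis
  risk groups, *Bacillus* in immunocompromise) need site-specific
  overrides.
* Exclusion is record-level; no patient-history lookup is performed.
* The T chart assumes event times are strictly ordered and unique;
  same-timestamp events must be merged or jittered upstream.
* The Wald interval is anti-conservative at very small counts; use
  `alpha` plus an external exact method if the balancing denominators
  are tiny.
* Weekly P-chart subgroups that straddle a phase boundary are split
  into one point per phase within the week.
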