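# Methods

## Model structure

`msseqsim` is a patient-level (first-order Monte Carlo) state-transition
model of relapsing multiple sclerosis under sequential disease-modifying
treatment (DMT).  A patient is characterized by age, an integer EDSS state
0–9, an alive flag (death is a separate absorbing flag, not an EDSS row),
the current treatment-line position within a sequence of up to five drugs,
years on the current drug, years since the last disease event, and
cumulative outcome counters.  The cycle length is one year: annual
transition matrices are the norm for EDSS models, and treatment effects
reported as 24-week confirmed-disability-progression (CDP) relative risks
are mapped onto the annual scale through rate scaling (below).

Within a cycle, events resolve in a fixed order — death, relapses, EDSS
transition, adverse event, line switch, stopping-rule check — which makes
runs exactly reproducible; sensitivity of results to this ordering is a
known caveat of cycle-based models and is not explored here.

### Mortality

The annual death probability is `1 − exp(−h(age)·m(EDSS))` with `h` a
background life-table hazard (integer ages 0–100) and `m ≥ 1` an
EDSS-dependent multiplier.  A patient who dies accrues nothing in that
cycle (no half-cycle correction anywhere; accrual always uses the state
occupied at cycle start — a documented limitation that slightly
underweights the death year).  Survivors at the life-table end (age 100)
are terminated.

### Relapses

Relapse counts are Poisson with annual mean `r(EDSS) · IRR`, where the
incidence rate ratio (IRR) versus placebo is the drug's relapse efficacy.
Each relapse subtracts a one-off utility decrement and adds a one-off cost
in its cycle; cycle utility may go below zero after large decrements (no
flooring — utility decrements are additive in this model family).

### Disability progression

The relative risk of CDP scales the *aggregate* probability of any EDSS
worsening: `w' = 1 − exp(RR · ln(1 − w))`, the exact annual-probability
analogue of a proportional-hazards effect.  Conditional on worsening, the
allocation among higher states keeps the natural-history proportions
(trials measure "progression", not per-state jumps); improvement
(back-transition) mass is untouched, and the stay probability absorbs the
difference.  Treatment therefore acts only on the worsening mass.

### Switching, line 1b, stopping

Any relapse or EDSS progression advances the patient one treatment line.
Adverse events (one aggregate annual discontinuation probability per drug)
also advance the line, except on line 1a of an escalation sequence, where
an adverse-event-only exit enters the alternative first-line slot 1b; a
cycle with both an efficacy event and an adverse event escalates to line 2,
treating efficacy failure as the dominant signal.  When a high-efficacy
drug opens the sequence the 1b branch does not exist.  Past the final line
the patient follows untreated natural history; no re-initiation is
modelled.  Patients aged ≥ 50 with ≥ 5 event-free years on lines 1a/1b/2,
or aged ≥ 70 with ≥ 10 event-free years on line 3, stop DMTs permanently.
Event-free time is measured across drugs (the clock does not reset at a
switch) — the alternative on-drug reading is a sensitivity-analysis
candidate.  Whether relapses on line 1b escalate exactly as from 1a is not
specified by the source model description; they are assumed to.

### Economics

Per surviving cycle: drug acquisition cost (first-year price in the first
cycle on a drug, subsequent-years price after), administration and
monitoring costs, EDSS-state healthcare cost, relapse costs, and societal
(productivity/caregiver) state costs; utility `u(EDSS) − d·relapses`.
Costs are discounted at 4%/yr and effects at 1.5%/yr (Dutch guideline;
both configurable), cycle 0 undiscounted.  List prices are integer Euros;
accrued totals stay real-valued and are rounded to integer Euros only in
report tables.  Net health benefit is `NHB = QALYs − costs/λ` with
λ = €50,000/QALY; reported NHB uses unrounded internal totals, which is why
a table's printed QALY/cost entries do not always reproduce its NHB row at
display precision.  Combined per-drug columns are unweighted means over
sequences (each sequence assumed equally likely).  Mean time to EDSS 6 is
reported over patients reaching it, always alongside the fraction reaching
it to avoid survivorship misreading.

## Randomness and common random numbers

Each cohort draws one uniform tensor `U[patient, cycle, 4]` up front from
its seed, with a fixed draw schedule (death, relapse, transition, adverse
event) for every patient and cycle whether used or not.  Patient *i* at
cycle *t* therefore sees identical uniforms in every arm sharing the seed —
common random numbers, which cancel most Monte-Carlo noise in paired
comparisons, PSA deltas and threshold searches.  Relapse counts come from
the inverse Poisson CDF of a single uniform (cross-checked against
`scipy.stats.poisson.ppf`), and transition targets from the cumulative row
in ascending EDSS order, so treatment-effect comparisons are monotone
pathwise: lowering IRR can never add relapses, lowering RR can never worsen
a transition, for the same uniforms.  The scalar per-patient path and the
vectorized cohort loop consume identical streams and are asserted
bit-equal in the tests.

## Sequence grammar

Drugs carry line eligibility (e.g. escalation drugs: 1a/1b; anti-CD20
mAbs: 1a/2; natalizumab/cladribine: 2–4; alemtuzumab: 4 only) and a
mode-of-action class; consecutive same-class switches are forbidden and
last-resort drugs may only occupy the final line label.  Enumeration emits
maximal sequences (no valid extension exists) in lexicographic order and is
verified against brute-force filtered permutations on small universes.
The shipped default rule set was reconstructed so that a second-line
anti-CD20 admits exactly 144 sequences: 7 escalation openers for lines
1a/1b with the S1PR-modulator class the only multi-drug first-line class
(7·6 − 3·2 = 36 ordered pairs) times four closures over
{cladribine, natalizumab, alemtuzumab} for lines 3/4.  The full eligibility
table behind that count is not published; the reconstruction is a test of
internal consistency, not a claim about the original table.

## Probabilistic sensitivity analysis

Each iteration applies one joint parameter draw to both arms and runs both
cohorts with common random numbers (500 iterations × 1,000 patients by
default).  Ratio parameters are lognormal with median at the point estimate
and `σ = (ln hi − ln lo)/(2·1.96)` so the published 95% CI becomes the
2.5/97.5 percentile range; utilities are beta and costs/relapse rates gamma,
moment-matched from a mean and a spread parameter (utility SE 0.03, cost
and rate CV 0.10 by default — the source publishes no CIs for these, so the
spreads are the generator's choice).  States with mean utility outside
(0, 1) fall back to a normal draw (a beta law is undefined there).  Sampled
utilities are re-sorted non-increasing and costs non-decreasing so every
draw respects the structural monotonicity invariants.  Acceptability is the
fraction of iterations with positive incremental NHB, ties counted one
half, reported with its binomial standard error and no smoothing.

## Threshold searches

Parity is defined under common random numbers and a tolerance of 0.005 NHB
(QALY units).  The drug price enters only linear cost accrual — simulated
trajectories are price-invariant — so NHB(price) is exactly affine under a
fixed seed: one cohort run at unit price yields the discounted
price-multiplier and the bisection (bracket [0, 2 × reference price], trace
recorded) runs on the exact affine function.  The candidate's first-year /
subsequent-year cost ratio is preserved as the price scales; a flat-price
alternative is selectable.  NHB(RR) does change dynamics, so the RR search
(bracket [0.2, 1.2]) re-simulates each trial value.  Prices are reported to
the nearest €100 and relative risks to two decimals, matching the field's
reporting convention.  Rituximab's two dose formulations share one pooled
IRR and differ only in cost, since the source prints a single pooled
relapse estimate.  When no candidate sequence is given, the search
substitutes the candidate into its highest-NHB enumerated sequence scored
under neutral assumptions; self-parity checks pass the mirrored reference
sequence explicitly.

## Synthetic parameter generator

The generator emulates the *structure* of the Dutch inputs of the
underlying sequence model, which are not published as data: utilities
follow a shifted-logistic decline through the published anchor
u(EDSS 2) = 0.782 (reaching slightly negative values at EDSS 8–9, as
utility scales permit); healthcare and societal state costs grow
geometrically with EDSS; the transition matrix is predominantly forward
(worsening mass ≈ 8–15%/yr per state with geometrically decaying multi-step
jumps, improvement mass ≤ 3%); relapse rates decline linearly from 0.7 to
0.3 per year across EDSS; mortality is Gompertz-shaped
(`h = 2.2·10⁻⁴·e^{0.094·(age−29)}`) with non-decreasing EDSS multipliers
from 1 (EDSS 0) to 3.6.  The four anti-CD20 drugs keep their published
efficacy and prices; their administration/monitoring costs and adverse-event
probabilities, and all ten other DMTs' parameters, are plausible filler
values ordered platform < moderate < high efficacy and flagged
`synthetic: true` in serialized output.  Scenario scale factors
(progression, relapse, cost intensity) and a seed jitter the quantitative
values without breaking any structural invariant (property-tested over
seeds).

What passing tests show — and do not.  The synthetic set exercises every
code path under realistic *shapes*, so the suite establishes arithmetic
correctness (oracle equivalence with a deterministic Markov-cohort
computation, effect recovery from pooled patient-cycles, PSA null
calibration, threshold convergence and monotonicity).  It does not
reproduce the published Dutch cohort magnitudes: with relapse rates held in
the prescribed 0.3–0.7/yr band and no age-related relapse decline (the
natural-history container indexes relapse rates by EDSS only), simulated
lifetime relapse counts and time on first-line treatment differ
substantially from the published figures, and absolute costs/QALYs are not
comparable.  Directional and structural conclusions (e.g. that a cheaper
anti-CD20 can tolerate worse progression efficacy at NHB parity) transfer;
magnitudes do not.

## Numerical choices and degenerate inputs

* Transition rows are validated row-stochastic to 1e-9; the treated stay
  probability is clipped at zero with the worsening scale guarded so an
  RR > 1 cannot push worsening beyond the available mass.
* The inverse Poisson CDF iterates the pmf recurrence (rates here ≪ 1, so
  two or three terms) with a hard cap of 400 terms.
* Serialization round-trips YAML floats bit-for-bit (shortest-repr floats);
  decimal-comma files are supported via a reader dialect flag.
* An unidentified progression efficacy is an explicit UNKNOWN sentinel, not
  1.0: deterministic runs refuse it with a pointer to the RR threshold
  search, which supplies trial values.
* A drug without a list price (ublituximab) can only be simulated through
  the price search, which scales a unit-price run.
* Cohort sizes: deterministic analyses use 10,000 patients (the model's
  standard cohort), PSA 500 × 1,000, threshold self-parity and monotonicity
  tests 5,000, module-level searches 3,000 — chosen as the package's
  standard problem sizes; the vectorized engine simulates 10,000 lifetimes
  in well under a second.

## Known limitations

No monthly cycles, no waning of treatment effect, no adverse-event
taxonomy (one aggregate probability per drug), no treatment re-initiation,
no age-dependence of relapse rates, no half-cycle correction, no
cost-effectiveness acceptability frontier over multiple willingness-to-pay
values, and no primary-progressive or secondary-progressive disease course.
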