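# Methods

## Model structure

A cohort state-transition (Markov) model with five states — Resolved ACS
(RA), Myocardial Infarction (MI), Cardiac Arrest (CAr), Revascularization
(Rv), Death (D) — advanced in 1-year cycles from age 30 to age 100, with
the entire cohort starting in RA. Transitions are memoryless given state
and age. The RA row of the published parameter table sums to exactly 1
(0.952 + 0.012 + 0.001 + 0.035), so the model has no background mortality
from the resolved state: death occurs only through the event states, whose
annual death probabilities are age-banded in 5-year bands from 30–34 to
80–84. Cohort proportions are tracked exactly (measure-1 cohort); the
"1000 patients" of the study population is a reporting scale only.

The high-intensity arm applies three hazard ratios (MI 0.77, CAr 1.07,
Rv 0.73) to transition probabilities into the corresponding event state.
Treatment effect is the only between-arm difference.

## Convention switches

The source material leaves several mechanical conventions open; each is
an explicit `ModelConfig` switch so any combination can be run, and the
`sweep` command enumerates all 128 combinations.

| switch | options (default first) | meaning |
|---|---|---|
| `residual_rule` | `to_RA`, `stay` | where event-year survivors go |
| `hr_transform` | `multiplicative`, `rate_based` | `hr·p` capped at 1, or `1−(1−p)^hr` |
| `hr_scope` | `all_inbound`, `from_RA_only` | which transitions the HRs touch |
| `half_cycle_correction` | off, on | half-weight first and last cycle |
| `over_84_rule` | `hold_last_band`, `truncate` | ages beyond the last mortality band |
| `discount_timing` | `begin`, `end` | cycle 0 undiscounted vs payments at year end |
| `discount_outcomes` | off, on | discount QALYs at the outcome rate |

Defaults for the first five follow the simplest literal reading of the
model description: survivors of an event year return to the resolved
state, hazard ratios multiply every inbound transition probability, no
half-cycle correction, and the 80–84 mortality band is held for the
lifetime tail beyond 84.

## Discounting of outcomes

The one deliberate departure from the stated methods is the
`discount_outcomes` default. The study text specifies a 3% annual
discount rate for both costs and utilities, but the published numbers are
not reproducible that way: with outcomes discounted at 3%, every one of
the 128 convention combinations yields a deterministic ICER between 2.8×
and 11.2× the published 31.8M IDR/QALY (the gap is, to first order, the
discounted incremental lifetime drug cost divided by the discounted QALY
gain). With costs discounted at 3% and outcomes left undiscounted, the
default convention set lands at 34.26M IDR/QALY (+7.6%), and the end-of-
year discount-timing variant at 33.26M (+4.5%). Two further published
observations corroborate this reading: the one-way sensitivity narrative
names the cost discount rate, but never the outcome rate, among the
influential parameters, and the acceptability of 0.99 at both WTP
thresholds is only consistent with the low ICER. The package therefore
reproduces the published analysis by default and offers
`discount_outcomes=True` for guideline-conformant practice. The fixture
itself carries the printed 3% outcome rate unchanged.

## Economic accumulation

Per cycle: state cost = occupancy-weighted direct medical cost (death
costs nothing); drug cost = annual statin price × proportion alive in
both arms (statin therapy is lifelong); QALY = occupancy-weighted
utility (death utility 0). Direct medical costs are treated as recurring
per cycle of occupancy. Discounting is end-of-cycle with cycle 0
undiscounted under the default `begin` timing. The ICER degenerates to a
dominance flag when the increments have opposite signs and to `undefined`
when |ΔQALY| < 1e-12. All arithmetic is in IDR; an optional user-supplied
exchange rate adds USD columns to CLI summaries (no rate is bundled).

## Probabilistic sensitivity analysis

Distribution families follow standard health-economics convention, fitted
by method of moments to the published mean and SE: Beta for probabilities
and utilities, Gamma for costs, Lognormal (moment-matched on the natural
scale) for hazard ratios. Discount rates are fixed in the PSA. The
stay-in-RA probability is not sampled independently — its printed SE
(0.095) is informational — but set to the residual of the three sampled
RA-row event probabilities, which preserves row-stochasticity by
construction. If a sampled event-state row's non-stay mass exceeds 1 in
any age band, the stay/switch entries are rescaled proportionally; draws
that still fail validation are redrawn (counted, capped at 100 per
iteration; in practice zero for the built-in table). Iteration *i* draws
from `default_rng([seed, i])`, so any prefix of a run is reproducible
independently of its length. All parameters are sampled independently,
and one draw drives both arms (common random parameters). The
probabilistic ICER is reported as ratio of means of the increments, with
median-of-ratios also exported.

## One-way sensitivity analysis

Each scalar parameter with an SE moves to mean ± 1.96·SE (`ci95`, clipped
to its domain) or ± 20% (`pct20`); the three age-banded mortality
families move all 11 bands together as single tornado entries; the two
discount rates sweep the guideline range 0–5%. Everything else is held at
base case and the deterministic ICER is recomputed at each bound; entries
sort by |ICER(high) − ICER(low)|. With outcome discounting off, the
outcome-rate entry has zero spread by construction.

One published ordering is not reproducible: the study reports the ICER
most sensitive to the resolved-ACS direct medical cost (dmcRA) and least
sensitive to the resolved-ACS utility (uRA), the HIS drug cost (cHIS) and
the cardiac-arrest hazard ratio. In this model dmcRA's printed SE is 1%
of its mean and acts only through the small between-arm difference in RA
occupancy, while cHIS (SE 10% of mean) multiplies every discounted
alive-year of the HIS arm and uRA (SE 10% of mean) scales most of the
QALY denominator; their spreads exceed dmcRA's by an order of magnitude
under any range rule, and the ratio spread(dmcRA)/spread(uRA) ≈
δdmc/(ICER·δu) ≪ 1 for any model in which both act through the same RA
occupancy. The corresponding acceptance test is left failing rather than
weakened. The model's own top-ranked parameter, the cost discount rate,
is at least consistent with its prominence in the published narrative.

## Synthetic parameter tables

`generate_random_parameter_set` produces structurally valid tables for
testing every pipeline stage independently of the built-in fixture:
RA-row events small with the stay probability as residual (or pushed
toward a near-1 event mass under `difficulty="extreme"`), banded death
probabilities increasing geometrically with age and leaving every row
feasible in its worst band, costs positive with SEs 1–20% of the mean,
utilities in (0.4, 0.9) (near 1 under extreme), hazard ratios in
(0.35, 1.45) (near 1 under extreme), and all SEs Beta/Gamma-feasible.
These tables exercise the model's structural assumptions; they do not
emulate correlations between parameters (none are modelled in the PSA
either) or real-world cost distributions, so tests passing on them speak
to numerical correctness, not to clinical realism.

## Verification

The cohort recursion is checked against an independent 200,000-patient
microsimulation (multinomial state counts through the same per-age
matrices) to within 0.5 percentage points per state per cycle; the
method-of-moments samplers against the published means/SEs over 10,000
draws (mean within 3 standard errors, SD within 10%); and the degenerate
zero-SE PSA against the deterministic run exactly. Problem sizes used
throughout — 1000 PSA iterations, 100 synthetic tables, 200k simulated
patients — match the published simulation count where one is stated and
otherwise were chosen to keep Monte Carlo error well inside the asserted
tolerances.

## Known limitations

No background (non-cardiac) mortality from the resolved state, so the
lifetime horizon overstates survival at old ages; no tunnel states or
time-in-state effects; no adherence or discontinuation modelling; no
correlation structure in the PSA; costs are 2016–2022 Indonesian tariffs
with no indexation. The published drug-cost range (27.4M–34.1M IDR,
labelled "annually") has an ambiguous denominator and is deliberately not
used as a check; the package exports lifetime discounted drug cost per
strategy instead.
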