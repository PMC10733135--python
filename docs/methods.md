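# Methods

## Scope and simulation design

The package estimates population variability (not uncertainty) of
aggregate exposure to one substance from personal care products (PCPs) and
household cleaning products (HCPs).  The unit of simulation is a surveyed
person: demographics (sex, nationality, body weight) and a product-use
profile (per product: a use-frequency answer, a use-amount answer, and the
application body parts).  Each person is simulated over a fixed 14-day
window, and two summary metrics are derived per replicate: the mean of the
14 daily exposures (long-term, "average daily") and their maximum (acute,
"highest daily").

Randomness is layered deliberately:

- **Use days** are realised once per person × product: diary-mode
  frequencies are copied verbatim (7-day diaries are tiled to 14 days,
  preserving the weekly pattern); interval-mode frequencies draw one
  habitual weekly frequency f ~ Uniform(lo, hi), convert it to
  p = min(f/7, 1), and draw 14 independent Bernoulli(p) day indicators.
  Day indicators are 0/1: multi-event days are not modelled (a frequency
  above 7/week saturates at one event per day).  This is a known
  limitation of the Bernoulli day construction.
- **Amounts** are drawn per use day (uniform within the answered category,
  or the fixed surveyed mean) and are shared across replicates: the
  replicate dimension represents brand variation, not behavioural
  variation.
- **Concentrations** are drawn per replicate — N_product draws per
  person × product from Bernoulli(occurrence) × P(concentration) — and
  held fixed over the 14 days, since a person's brand does not change day
  to day.  N_product defaults to 100 (50 in the case study; see sizes
  below).
- **Aggregation** randomly pairs the replicate samples of different
  products (an independent uniform permutation of replicate indices per
  product per person) before summing across products per day.  For dermal
  load, sums are accumulated within each body part first; the body part
  with the highest daily load is the day's exposure.  For the systemic
  metric the Total group equals PCP + HCP exactly, pointwise; for dermal
  load it does not (the max over parts is taken after combining groups).

RNG streams are hierarchical: every (person, product) pair gets its own
stream keyed by (seed, person index, hash of product id), and pairing and
survey merging use separate tagged streams.  Adding or removing a product
therefore does not perturb any other product's draws, and identical
configurations reproduce results bit for bit.

## Exposure metrics and units

Amounts are in g/event, concentrations in mass fraction (g/g), dermal
load in µg/cm², systemic dose in mg/kg bw/day.

Dermal load applies the full event amount to *each* listed application
body part with that part's retention factor and surface area; the
alternative (splitting the amount across parts) is not used because the
survey records where a product is applied, not how it is divided.  The
denominator is the whole body-part surface area (configurable), not the
product's actual application area — a deliberate, documented reading of an
ambiguous convention; users can override `surface_areas` to express
smaller application areas.

Default surface areas (cm², adult): trunk 5690, head 1305, arms 2282,
hands 860, legs 5528, feet 1310.  Default retention factors: 1.0 for
leave-on PCPs, 0.01 for rinse-off PCPs and for HCP hand contact.  All are
overridable configuration, never baked into computations or tests.

Systemic dose sums EF × f_abs over the selected routes (oral, inhalation,
dermal), assuming exposure is linear in the amount used.  Exposure
fractions are user input; the well-mixed-room helper derives an
inhalation EF from an instant-release scenario,
D = A·(1−e^{−qt})/(qV)·R_inhale, EF = D/A.  Linearity ignores saturation
phenomena (evaporation, dermal absorption kinetics), which is why EF > 1
triggers a warning rather than silently clipping.

## Concentration model

Occurrence is the fraction of marketed products of a type containing the
substance; sampled concentrations are 0 with probability 1 − occurrence.
Supported distributions: point, uniform, normal, lognormal, triangular.
Normal and triangular draws are truncated at 0 by rejection (mass
fractions cannot be negative); all draws are capped at 1 g/g with a
warning.  Lognormals are parameterised internally as (µ_log, σ_log) of
natural logs; configuration also accepts median + GSD.

Fitting from a measurement campaign: occurrence = positives / total
sampled (no continuity correction); ≥ 2 positive samples → lognormal by
maximum likelihood on log values (mean and 1/n-variance of the logs);
exactly 1 positive sample c → Uniform(c/10, 10c); 0 positives →
occurrence 0.  MLE (rather than moment matching on the original scale)
was chosen because it is the standard fit for log-symmetric concentration
data and is exactly invertible in the recovery tests.  HCP products are
typically pooled by generic product form (liquids, sprays, wipes): a
form-level spec applies to every product of that form, with explicit
per-product specs taking precedence.

## Survey model and merging

Categorical survey answers are stored already resolved to numeric
intervals; the default label table maps "<1/week" → [0, 1] … "1/day" →
[7, 7] and the open-ended "≥2–3/day" to [14, 21] events/week (an explicit
convention — open categories have no canonical width).  HCP quantity
measures (sprayings, wipes, dilutions) are assumed pre-converted to grams
in the input schema.  Additional demographics (age, education, skin type)
are accepted by the schema but ignored by the engine.

PCP and HCP surveys are merged by sex and nationality only: each PCP
person keeps their demographics and gains the HCP profile of a uniformly
sampled (with replacement) HCP person in the same (sex, nationality)
cell.  Product use is assumed uncorrelated *between* the groups; co-use
*within* each group is whatever the survey (or generator) contains.  The
Dutch and European PCP surveys cover different products and are never
combined; selecting a country selects the matching PCP survey.

Population percentiles pool all person × replicate summary values with
equal person weights and use linear interpolation between order
statistics.  The "exposed only" filter keeps persons with any nonzero
total exposure in any replicate on any day, and is applied uniformly to
all table rows.

## Synthetic surveys

The generator emulates the structure of three real survey types: a
Dutch-style PCP survey (default 516 persons, 32 products, categorical
frequency/amount answers), a European diary-style PCP survey (21
products, 14-day diaries, fixed weighed amounts) and a European HCP
survey (5 cleaner types across liquid/spray/wipes forms, hands-only
application).  Body weights are lognormal (median 74 kg, GSD 1.18); the
default HCP nationality weights include NL so the HCP survey can be
merged with the Dutch PCP survey.

Co-use correlation is induced by a single latent "usage propensity" per
person added to every product's ownership log-odds (SD 1.0 by default).
This matters: the tier-1 vs person-oriented contrast only exists if heavy
users of one product tend to be heavy users of others.  What the
generator does **not** emulate: real marginal frequency/amount
distributions of any actual survey, age structure, seasonal patterns, or
correlations between specific product pairs beyond the one-factor
propensity.  Passing tests therefore demonstrate correctness of the
simulation machinery on structurally realistic inputs, not agreement with
any published population exposure estimate.

## Case study

The shipped case study reproduces the *structure* of a preservative
(methylisothiazolinone-like) dermal-load assessment: synthetic
measurement campaigns of 20 samples per PCP product (positive counts
cycling through 4, 6, 0, 3, 8, 1, 5, 7, i.e. a mean occurrence near 0.2
for a widely-used preservative, with the 0- and 1-positive fitting rules
still exercised) and per HCP form (liquid 8, spray 6, wipes 1 of 20);
positives lognormal with median 5×10⁻⁵ g/g, GSD 2.5.  The highest-day
aggregate dermal load is summarised as a percentile table, contrasted
with the tier-1 additive estimate (sum of per-product P95/P99
single-product exposures, computed from the same runs and seed so the
contrast isolates the aggregation method), and compared against an
acceptable exposure level of 7.4×10⁻² µg/cm².  Published percentile
tables for the real assessment depend on confidential survey and
concentration data; the case study makes no quantitative claim about
them, only the qualitative ordering tier-1 > aggregate at high
percentiles.

## Problem sizes and numerical choices

Default sizes — 516 + 400 persons, ≈ 41 products, N_product 50, 14 days —
run the full case study in a few seconds on one core; tests use smaller
populations (tens to hundreds of persons, N_product 4–50) chosen so every
stochastic check has analytic error bounds (3 standard errors for means
and proportions, χ² at p > 0.01 for distributional comparisons) rather
than tuned tolerances.  Degenerate inputs are defined, not rejected:
lo = hi intervals are point masses, occurrence 0 yields exact zeros,
empty use lists yield zero exposure rows.  Ties in the body-part maximum
resolve to the value (parts are never compared by name).

## Known limitations

- One event per day at most; no within-day time resolution and no
  carry-over of indoor air between days.
- No uncertainty quantification: fitted concentration parameters are
  treated as known; only population variability is propagated.
- No dermal absorption kinetics or evaporation; exposure fractions are
  linear by assumption.
- Population stratification is limited to sex and nationality.
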