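# Methods

## Measures

### Catastrophic health expenditure

Let `x_i` be household `i`'s total expenditure, `food_i` its food
expenditure, `nf(x_i) = x_i − food_i` its capacity to pay (non-food
expenditure), and `T_i` its out-of-pocket (OOP) health payments, all per
household per period in a common currency.  For a threshold `z ∈ (0, 1)`
and a denominator `d_i ∈ {x_i, nf(x_i)}`:

- exceedance indicator `E_i = 1{T_i/d_i > z}` — *strictly* greater: a
  household exactly at the threshold is not catastrophic;
- head count `H = Σ w_i E_i / Σ w_i` (sampling weights `w_i` default to 1,
  giving the plain `1/N` estimator);
- household overshoot `O_i = E_i (T_i/d_i − z)`, mean overshoot
  `O = Σ w_i O_i / Σ w_i`, mean positive overshoot `MPO = O/H`
  (reported as undefined, not 0, when `H = 0`);
- concentration index `C = 2 cov_w(outcome, r) / μ` with `r` the weighted
  fractional rank of the living standard and `μ` the weighted outcome
  mean; `C_E` uses outcome `E_i`, `C_O` uses `O_i`;
- rank-weighted measures `H_w = H (1 − C_E)` and `O_w = O (1 − C_O)`,
  algebraically identical to weighted means with rank weights `2(1 − r_i)`
  (poorest ≈ 2, richest ≈ 0).

The fractional rank after a stable ascending sort is
`r_i = (cumulative weight below i + w_i/2) / W`; with equal weights this
is the textbook `(i − ½)/N`.  Its weighted mean is exactly ½, and the
covariance is the weighted *population* covariance — both are what make
`H(1 − C_E)` agree with the direct rank-weighted sum to machine precision,
an identity the test suite asserts at 1e−10.  Ties are broken by input
order (per-unit ranks); a `tie_rank="average"` option assigns tie groups
their midpoint rank.  Both choices are deterministic; with continuous
expenditure data they coincide almost surely.

The rank variable defaults to the same living-standard measure as the
share denominator (total expenditure for total-expenditure shares,
capacity to pay for capacity shares), at the household level and
unadjusted for size; it can be overridden per call.

### Impoverishment from health payments

Per-capita expenditure is `y_i = x_i / s_i` with `s_i` the household size
(no adult-equivalence scale), and net-of-health-payments expenditure
spreads the household's OOP evenly over members:
`y_i^net = (x_i − T_i)/s_i`.  For a poverty line `PL` (same units and
period as `y`), poverty status is strict (`y < PL`; a person exactly at
the line is not poor) and all sums are person-weighted (`s_i w_i`):

- head count `HP = Σ s_i w_i p_i / Σ s_i w_i`;
- gap `G = Σ s_i w_i p_i (PL − y_i) / Σ s_i w_i` (averaged over *all*
  people, poor and non-poor);
- normalized gap `NG = G/PL`; normalized mean positive gap `NMPG = NG/HP`
  (undefined when nobody is poor).

The impoverishment effect is the paired gross/net comparison with
absolute (`net − gross`) and relative (`(net − gross)/gross`) changes per
measure; net measures dominate gross ones whenever any `T_i > 0`.  The
person-weighted household estimator is tested for exact equality against
literally expanding each household into `s_i` individuals.  Scaling the
absolute head-count change by an external population total (a caller
input, not bundled) converts the rate into a number of people pushed into
poverty.

Validation enforces `T_i ≤ x_i` (OOP is a component of total
expenditure), so net expenditure is non-negative by default; a
`floor_net_at_zero` flag exists for data admitted under permissive
validation.  Two poverty lines ship as presets in 2012-price MNT/month —
the Mongolian national line (118,668) and the World Bank $1.90/day 2011
PPP line (34,769.6, taken as given; the days-per-month convention behind
the conversion is not reconstructed).

### Descriptives

Weighted quintiles of a living standard (per-capita expenditure by
default) split the cumulative weight at 20/40/60/80 %; a household
straddling a cut goes to the quintile containing the midpoint of its own
weight span, and ties keep input order, so each quintile holds 20 % of
the weight up to one household.  Utilization tables report per-group
proportions with a Pearson chi-square test of independence (labelled as
such in the output, and skipped with a flag on degenerate tables); OOP
tables report group means and the Q5/Q1 ratio.

## Tunable parameters that matter

| parameter | default | meaning |
|---|---|---|
| threshold `z` | 0.05/0.10/0.15/0.25 (total); 0.15/0.25/0.40 (capacity) | catastrophic budget-share cutoffs; 10 % of total and 40 % of capacity are the conventional headline pair |
| `weights_mode` | `none` | sampling weights are opt-in; the defining estimators are unweighted `1/N` forms |
| poverty line `PL` | preset or numeric | per person per period, same units as expenditure |
| validation policy | `strict` | `drop` removes offending rows, `clamp` repairs (negatives → 0, food/OOP capped at total), both with per-rule tallies |
| `tie_rank` | `unit` | fractional-rank tie handling |

## Synthetic survey generator

The generator emulates what the analysis assumes of a household budget
survey; every dataset it emits passes strict validation.  Per household,
in a fixed draw order from one seeded `numpy` Generator stream (sizes,
per-capita expenditure, OOP-zero indicators, OOP noise, urban
indicators — food shares are deterministic given expenditure):

- size `~ 1 + Poisson(mean − 1)` (default mean 3.6);
- per-capita expenditure log-normal (default `μ=12.10`, `σ=0.55` in log
  MNT/month — median ≈ 180k, right-skewed);
- food share `clip(1.55 − 0.10·log(pc), 0.05, 0.95)` — an Engel curve
  declining from ≈ 44 % for the poorest to ≈ 23 % for the richest;
- OOP zero with probability 0.35, otherwise
  `oop_scale · total^1.6 · LogNormal(0, 1) · (1.5 if urban)`, capped at
  non-food expenditure so both budget-share denominators stay coherent
  (`T ≤ nf(x) ≤ x`); urban probability 0.63.

Elasticity 1.6 makes health spending a luxury good, producing a positive
`C_E` and a roughly tenfold Q5/Q1 mean-OOP gap.  The defaults ship as the
preset `hses2012-like`: `oop_scale = 5.8e-6` was fixed once with the
module's own bisection calibrator so the preset lands near a 5.5 % head
count at `z = 10 %` of total expenditure, and the expenditure parameters
place the 118,668 MNT line near the 22nd percentile of per-capita
expenditure, matching the scale of a 2012 Mongolian-style survey.  These
are qualitative calibrations of scale and shape, not reproductions: the
generator has no within-household correlation structure, no survey design
(strata/PSU), no item-level consumption, no measurement error, and
independent log-normal noise — so passing tests demonstrate estimator
correctness and qualitative gradients, not agreement with any real
microdata estimate.

`generate_calibrated` rescales `oop_scale` by bisection (bracket
expansion, then up to 60 iterations) until the realized head count at a
chosen `(z, denominator)` hits a target within tolerance; the random
draws are held fixed, so the head count is a deterministic step function
of the scale and convergence is to within one household's weight.

## Numerical choices and degenerate inputs

- All computation is full precision; rounding to display precision
  happens only in the text renderer (`csv`/`json` outputs carry raw
  floats), because rounded intermediates visibly corrupt derived
  identities such as `O_w = O(1 − C_O)`.
- `MPO` and `NMPG` are `None` (rendered "undefined") when their
  denominators are zero; relative changes are `None` where the gross
  measure is zero.
- A household with zero capacity to pay and zero OOP has share 0; OOP
  above capacity to pay (possible because validation bounds food and OOP
  by the total separately, not jointly) clamps the capacity share at 1.0
  with a warning, keeping shares interpretable as budget fractions.
- Concentration indices require `N ≥ 2` and a nonzero outcome mean; the
  `H = 0` case is caught upstream (indices set to 0 and `H_w = 0` in the
  table, since no exceeders means nothing to distribute).

## Problem sizes in the checks

The test suite exercises the estimators at the survey's own scale where
the property demands it: generator parameter recovery at n = 50,000
(99.9 % binomial interval), gradient and calibration checks at
n = 20,000, the O(N²) concentration-index oracle up to N = 200, and the
person-expansion poverty oracle up to N = 100.  The whole suite runs in a
few seconds.

## Known limitations

- No survey-design variance estimation: weights enter point estimates
  only; no standard errors or confidence intervals for H, O, C or the
  poverty measures.
- No decomposition of the concentration index, no poverty severity
  (FGT(2)) measures, no Pen's-parade plotting.
- Period harmonization across recall windows is the caller's
  responsibility (the reader's per-column multipliers are the supported
  mechanism); no PPP or inflation adjustment is performed internally.
- The chi-square test for utilization tables is an implementation choice
  labelled in the output; other tests of proportions are defensible.
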