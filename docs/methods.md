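# Methods

This note documents the statistical model behind `ringanchor`, the
defaults it ships with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Conventions

- Calendar axis: integer astronomical AD years; cal BP = 1950 − AD. No
  year-zero special-casing is applied — the package targets the first
  and second millennium AD, far from the BC/AD boundary, and the
  convention is stated here rather than branched on.
- Conventional ¹⁴C ages use the Libby mean life (8033 yr). A per-mil
  activity change δ maps to an age shift of 8033·ln(1 + δ/1000) ¹⁴C yr;
  a *rise* in activity is a *drop* in age. Reporting of spike magnitudes
  rounds to the nearest ten ¹⁴C yr ("about 70", "about 100"); all
  internal arithmetic is full precision.
- Ring numbering: waney edge (final growth ring) = 0, penultimate ring
  = −1, inward. Ring r of an item felled in year x grew in year x + r.
  The χ² statistic is often written with positive ring counts and
  C(x − rᵢ); the two are the same formula.

## Reference objects

Two kinds of reference series are kept deliberately distinct:

- **CalCurve** (IntCal-style): arbitrary-resolution curve interpolated
  linearly — both mean and σ, since curve files define no between-node
  σ and linear is the common convention — onto a 1-year grid. Used for
  stage 1. Grid resolution is fixed at 1 yr because the question asked
  of the data is single-year.
- **AnnualReference** (B2018-style): strictly consecutive annual values,
  exact lookup, no interpolation. Used for stage 2, where the
  single-year structure *is* the signal. The file reader accepts the
  generic 3-column form (year AD, ¹⁴C age BP, 1σ); no assumption is made
  about any particular published version's extra columns.

## Stage 1: wiggle match

With fixed ring gaps the D_Sequence-style model has a single free
parameter (the waney-edge year x), so the posterior is computed exactly
on the integer-year grid — a deterministic alternative to the MCMC used
by general-purpose calibration software, which approximates the same
distribution. The prior on x is flat over the trial window (default:
every x for which all ring years lie on the curve). Likelihoods are
evaluated in log space and renormalized with log-sum-exp, so poor
absolute fits cannot underflow to an all-zero posterior; a flat
posterior and any ring sitting > 10 combined σ from the curve at every
trial year raise explicit warnings on the result rather than errors.

Posteriors are discrete per-year masses (not continuous densities). HPD
intervals take grid years in descending mass order until the requested
level is reached, breaking exact ties toward the earlier year
(documented, deterministic), then merge consecutive years into maximal
runs; the captured mass therefore lies in [level, level + one cell].

`sum_densities` implements the plain normalized arithmetic mean of
posteriors (the Sum construction). It does not model bounded phases or
group priors; averages produced with such priors in other software can
differ slightly.

## Stage 2: χ² anchoring

The statistic is the classical pattern-matching χ²

    χ²(x) = Σᵢ (Rᵢ − C(x+rᵢ))² / (δRᵢ² + δC(x+rᵢ)²)

evaluated exactly per trial year; no vertical offset between sample and
reference is fitted, so a match over n rings has n − 1 degrees of
freedom (one parameter, x, is chosen by the scan). The 95% critical
value for the canonical six-ring window is χ²(0.95, 5) = 11.07, via
scipy's regularized-incomplete-gamma inverse. Ties at the minimal χ²
report the earliest year and set a flag. The acceptance set is every
scanned year with χ² ≤ critical; a best year failing its own critical
value is reported as `poor_fit` with no felling year.

**Event-ring window.** The window that must contain the spike follows
from the stage-1 interval [W_lo, W_hi] and the event year E as
[E − W_hi, E − W_lo] (e.g. AD 1019–1024 and AD 993 → rings −31…−26);
the window is *derived*, not hard-coded. Two guards apply:

- If the window extends beyond the item's preserved rings, the event
  ring may simply not be in the wood, and the item is reported
  `no_anchor` (never silently clipped): this is exactly the situation
  of a short series that ends after the event.
- A very sharp stage-1 interval can shrink the window to one or two
  rings — too few for the test (d.f. 0) and, worse, possibly entirely
  on one side of the spike boundary, which leaves late trial years only
  weakly penalized. The window is therefore padded, alternating to both
  sides within the preserved span, to a minimum of six rings
  (`min_window_rings`), the canonical window size for this test.
  Windows already ≥ 6 rings are untouched.

The stage-2 scan runs over the stage-1 interval widened by
`trial_margin` (default 2) years on each side, clipped to years the
reference can cover.

## Replicates and laboratory offsets

Replicate determinations of one ring are combined by inverse-variance
weighting (combined σ = (Σwᵢ)^(−1/2)); consistency uses the Ward–Wilson
T = Σwᵢ(Rᵢ − R̄)², referred to χ² with n − 1 d.f. The inter-laboratory
offset is the inverse-variance weighted mean of per-ring differences
(lab B − lab A, direction reported explicitly), each difference carrying
variance σ_A² + σ_B²; |offset| > 2σ is flagged as significant. Published
offsets computed by other estimators (e.g. regression) may differ
slightly from this weighted-mean-of-differences definition.

## Synthetic data

`make_reference` builds an annual series: linear baseline (default
1110 BP at AD 940 falling 1 ¹⁴C yr per calendar year — the approximate
level and slope of the late-first-millennium atmosphere) minus the age
shift of magnitude·decay(y), where decay is 0 before the event year, 1
at the event year, then exponential with an 8-yr half-life. The spike
shape after the rise is a documented guess — only the single-year rise
magnitude matters for anchoring — and `signature_lag` shifts the onset
by whole years if the opposite ring/drop convention is wanted. With the
default lag of 0, the last pre-event ring keeps the elevated age and the
event-year ring shows the full drop. Reference σ defaults to 10 ¹⁴C yr,
typical of combined annual datasets.

`sample_tree` gives each ring the reference age of its growth year plus
Gaussian noise of the stated per-mil σ (default 2.0‰ ≈ 16 ¹⁴C yr;
high-precision AMS on cellulose achieves 1.5–2.5‰). Replicates beyond
the first are attributed to a second laboratory and carry the scenario's
systematic offset. All randomness flows from the scenario seed. In
noise-free scenarios the quoted σ is floored at 10⁻⁶ ¹⁴C yr so
measurement records remain valid; the sampled ages equal the reference
exactly.

What the generator does **not** emulate: carbon-cycle physics of the
production event, ring-width variation, missing or false rings,
regional/seasonal growth offsets, pretreatment chemistry effects, or a
calibration curve with its own error structure (the stage-1 curve is a
5-yr moving average of the annual reference, emulating only the
*attenuation* of single-year features in smoothed curves). Passing
recovery tests therefore demonstrate the statistical machinery under
idealized ring counting and an internally consistent reference — not
robustness to dendrochronological pathologies.

`recovery_experiment` repeats simulate → stage 1 (vs the smoothed
curve) → window derivation → stage 2 (vs the annual reference) and
reports the fraction of trials whose best year equals the true felling
year, with binomial Monte-Carlo σ, plus the mean χ² acceptance-set size
(≈1 under a strong spike; large when no spike is present, i.e. no
exact-year power). Trials whose stage-1 window cannot produce a valid
in-span ring window are counted as failures with acceptance-set size 0.

## Problem sizes used in the shipped checks

The bundled tests and examples use 30–60-year references, trees of 9–80
rings, and Monte-Carlo batches of 20–200 trials — sizes at which every
behaviour of interest (spike anchoring, no-spike null, monotonicity in
noise and magnitude) is already unambiguous and the whole suite runs in
seconds on one core.

## Known limitations

- Stage 1 assumes the calibration curve's errors are independent between
  years; real curves have correlated errors, so HPD intervals on real
  data can be mildly optimistic.
- No systematic sample-vs-reference offset is fitted in stage 2. If a
  real offset exists (species, regional or laboratory), χ² is inflated
  uniformly across trial years; the argmin is unaffected but the
  acceptance set shrinks.
- The felling-*season* (earlywood/latewood anatomy) is outside scope, as
  are marine-reservoir corrections and Southern Hemisphere curves.
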