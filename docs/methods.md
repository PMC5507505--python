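# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not demonstrate
about real histological material.

## Measurement model

A tooth is represented by two ordered sequences of measurements taken on
a labiolingual thin section:

* **Prism segments** — spans traced along single enamel prisms from the
  enamel-dentine junction (EDJ) outward, each with a length (μm, ≤ 200 μm
  by protocol) and repeated cross-striation counts from two observers.
  Counts are stored raw and averaged at load time; averages may be
  half-integers and are never rounded at segment level.  Day values stay
  at full precision internally; report tables round half-away-from-zero
  to whole days.
* **EDJ intervals** — lengths of junction between biological landmarks
  (accentuated or physiological lines) with the days taken to form them,
  located by cumulative fractions of the total prenatal EDJ measured from
  the dentine horn toward the cervix.

If no neonatal line (NL) is present the individual died at or very soon
after birth and all observable enamel is treated as prenatal.  Missing
optional fields (crown area, total EDJ length) are recorded as absent,
not zero.

## Robust through-origin regression

The pCFT predictor is the slope-only model `count = b·length`, estimated
in two stages:

1. preliminary slope `b0 = median(yᵢ/xᵢ)` (breakdown point ½), residual
   scale `s = MAD(y − b0·x)/0.6745`, held fixed;
2. IRLS with Tukey bisquare weights (tuning constant c = 4.685, 95 %
   Gaussian efficiency) from the OLS-through-origin start, converging at
   relative slope change < 1e-10 or 100 iterations.  This minimizes the
   bounded objective `J(b) = Σ ρ((yᵢ − b·xᵢ)/s)`, which the test suite
   verifies against an exhaustive grid search (step 1e-5).

Degenerate inputs (fewer than 3 points, non-positive lengths) raise; in
the exact-fit case (`s = 0`, a majority of points exactly collinear) the
slope is the least-squares fit of the collinear subset, so the estimator
coincides with OLS on noiseless constant-rate data.

95 % slope bounds are Wald-type from the M-estimator sandwich variance
with a `n/(n−1)` small-sample factor and a t(n−1) quantile.  A published
interval for this kind of fit may be constructed differently (e.g. by
bootstrap), so reported bounds are diagnostics, not reproduction targets.
The adjusted R² uses the *uncentered* total sum of squares — the only
coherent definition with a zero intercept, and an optimistic one; it
should be read as a lack-of-fit screen, not as explained variance.

The same estimator applied to (EDJ length, days) pairs gives the coarser
EDJ-based predictor; a through-origin polynomial fit (degree 2–3, no
constant term) is available to confirm that curvature does not improve on
the straight line for prism data.

Inter-observer reliability is summarized by the intraclass-style
coefficient `R = 1 − s_w²/(s_b² + s_w²)` with `s_w² = var(d)/2` the
within-pair variance of the count differences and `s_b²` the variance of
pair means, alongside the paired t-test.  R is invariant to a constant
shift between observers; the t-test detects exactly such shifts.

## Rates, regions and smoothers

DSR = segment length / day count; EER = interval length / days (both
μm/day).  For regional comparisons the EDJ fraction axis is split at 0.70
and 0.90 into cuspal-middle, middle-neonatal and neonatal portions —
unequal on purpose, because the cuspal EDJ extends so fast that a short
formation time covers a long stretch of junction.  An interval belongs to
the region of its fraction midpoint; a midpoint exactly on a boundary
goes to the earlier (more cuspal) region.  Prism segments carry no EDJ
position of their own, so for regional DSR summaries a segment inherits
the region of the same-index EDJ interval of its tooth and segments
without a matching interval are omitted; whether a "cuspal-middle EER"
should be read as the first interval's rate or as the region aggregate is
left to the caller (both are computable from the returned value lists).

The topographic DSR surface is a thin-plate spline (r² log r kernel,
affine part unpenalized) on axes normalized to the unit square, with a
ridge penalty on the basis coefficients selected by generalized
cross-validation over a 21-point log-spaced grid (1e-8…1e2).  The
explained-deviance figure is 1 − RSS/TSS about the mean rate.  Smoothed
display grids are floored at 1e-6 μm/day; statistics never use the floor.

Growth profiles (cumulative EDJ length vs cumulative days, with an
implicit (0, 0) origin) are smoothed by loess: local linear fits with
tricube weights and nearest-neighbour span 0.75 (configurable), evaluated
directly at grid points rather than interpolated between sample fits.  An
isotonic pass (`cummax`) then enforces that EDJ length never decreases.
Nearest-neighbour loess does not preserve concavity exactly — bandwidth
jumps produce convex wiggles comparable to the local curvature — so
deceleration claims are tested on the raw cumulative profile (where they
are exact) and on first-third vs last-third smoothed slopes.  Fewer than
4 intervals yields a raw-points-only profile with a finding.

## Gestational arithmetic and classification

With gestation G (default 273 days) and crown initiation between
gestational days I_min–I_max (default 91–140), full-term pCFT lies in
[G − I_max, G − I_min] = [133, 182] days.  The working threshold is more
conservative, 120 days, motivated by a gap in the empirical pCFT
distribution; classification is inclusive (pCFT ≤ threshold ⇒ pre-term)
and always applied to unrounded values.  `suggest_threshold` scans gaps
between order statistics inside a window (default [100, derived
full-term minimum]) and returns the lower edge of the widest gap — ties
to the first — as advice; it never silently replaces the configured
threshold.  Pre-term birth and perinatal death are distinct events, so
pre-term individuals who nonetheless formed an NL are flagged separately.

## Statistical conventions

* Mann-Whitney U: midrank ties (0.5 credit), headline statistic
  min(U_x, U_y) with both one-sided statistics exposed (reported W values
  in the literature are software- and group-order-dependent); p from the
  tie-corrected normal approximation with 0.5 continuity correction.
* Kruskal-Wallis: tie-corrected H, χ² with k − 1 df (scipy).
* Levene: ANOVA on absolute deviations, mean-centred by default;
  median-centring (Brown-Forsythe) by flag.
* ANCOVA interaction: extra-sum-of-squares F between
  `y ~ x + group` and `y ~ x * group` (statsmodels OLS).
* Summary t: pooled-variance two-sample t from (mean, sd, n) pairs,
  df = n₁ + n₂ − 2.
* Percent errors use the direct count as denominator.
* Two conventions exist in the wild for the sign of pCFT residuals
  (direct − predicted vs predicted − direct); this package reports
  direct − predicted throughout.

## The synthetic generator

The simulator draws, per individual: initiation uniform over gestational
days 91–140; gestation Normal(273, 7) truncated at ≥ 259 days (37 weeks,
the standard obstetric pre-term cut) for full-term births and uniform
over 196–258 days for pre-term ones; post-natal survival such that
~5/18 of individuals survive ≥ 10 days and form an NL (survivors uniform
10–120 days, the rest 0–9 days).  Crown growth follows
`EER(t) = E_inf + (E0 − E_inf)·exp(−t/τ)` with defaults E0 = 80,
E_inf = 25 μm/day, τ = 40 days — chosen to give cuspal extension rates
near 50–60 μm/day decelerating sharply toward ~30 μm/day, and prenatal
EDJ lengths of a few millimetres, the ranges seen in deciduous incisor
material.  EDJ length is the fixed-step (0.1 day) trapezoid integral of
EER, closed-form when E0 = E_inf, so interval lengths telescope exactly.
The secretion field is `d(w) = d_edj(1 + γ·w)` with d_edj = 4.0 μm/day
and γ = 0.25 (≈ 1 μm/day gain across the enamel thickness), tapered by
20 % over the cervical-most 10 % of the EDJ; the taper magnitude is not
empirically constrained and is config-exposed.  Measurement emulates the
protocol: segments ≤ 200 μm at random inner-enamel depths, per-observer
counts with additive Gaussian day noise (sd 1.0, floored at 0.5 days;
integer-count mode by flag), 3–8 EDJ intervals with jittered landmark
times.  Per-individual seeds derive deterministically from the cohort
seed; identical (config, seed) yields bit-identical cohorts.

What the simulator does **not** model: postnatal enamel, Retzius-line
periodicity, accentuated stress lines other than the NL, prism
decussation/section-obliquity errors (observer noise is unbiased
Gaussian, real miscounts are likely skewed), diagenetic surface loss, and
correlations between initiation age and growth rates.  Passing recovery
tests therefore demonstrate the *estimators'* correctness under the
stated generative assumptions, not the fidelity of those assumptions to
any particular archaeological assemblage.

## Problem sizes and calibration checks

Test and script problem sizes are chosen to exercise the estimators well
past the reference-series scale while staying quick: recovery cohorts of
50 (noiseless) and 200 teeth (noisy), 20-seed sign checks for the
time–EER correlation, 200-seed null calibration for regional rank tests
at the 18-tooth study size, and 500 simulated null datasets for the
Levene and ANCOVA type-I error checks (target 0.05 ± 0.02).

## Known limitations

* The robust confidence bounds are asymptotic; at very small n (< 10
  segments) they undercover.
* The GCV ridge search assumes at least ~20 well-spread surface points;
  strongly clustered designs may select the weakest penalty.
* The EDJ-based predictor inherits the full nonlinearity of extension
  deceleration and is intentionally reported as a rough indicator only.
* Reference-table statistics inherit the table's printed rounding; pooled
  rate means recomputed from per-tooth (mean, n) pairs differ from
  segment-level pooling by up to ~0.01 μm/day.
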