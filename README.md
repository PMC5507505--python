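# prenatal-enamel

Histomorphometry toolkit for the **prenatal enamel** of human deciduous
central incisors: estimation of prenatal crown formation time (pCFT) from
daily incremental markings, daily secretion rate (DSR) and enamel
extension rate (EER) profiling, and pre-term vs full-term birth
classification — aimed at bioarchaeologists and dental histologists
working with perinatal dental material.

## The science in brief

Enamel grows incrementally: each **cross-striation** along an enamel
prism marks one day of matrix secretion, so counting striations from the
dentine horn to the neonatal line (or the most cervical preserved enamel)
gives the prenatal crown formation time directly.  When daily markings
are not readable everywhere, pCFT must be predicted from what can be
measured.  The core estimator here is a **robust linear regression
through the origin** of cumulative cross-striation counts *Y* on prism
length *X* (μm):

    Y = b·X,        pCFT ≈ b · (total prism path length)

The zero intercept encodes a physical fact — no prism length means no
days of secretion — and makes the prediction *additive over segments*:
summing per-segment predictions equals predicting from the total length.
Published estimators with a non-zero intercept re-add that intercept once
per measured segment, a bias that grows with how finely the prism path is
partitioned.  The reciprocal 1/b is the implied overall DSR (μm/day).
The fit is an M-estimator (Tukey bisquare loss, MAD scale, IRLS) so that
occasional miscounted segments do not drag the slope.

Around that core the package provides:

* elementary rates (`segment_dsr`, `interval_eer`) and their regional
  summaries along the enamel–dentine junction (EDJ), partitioned into
  cuspal-middle (0–70 %), middle-neonatal (70–90 %) and neonatal (last
  10 %) portions;
* a thin-plate-spline DSR surface over (crown position × depth) with a
  GCV-selected ridge penalty, and loess growth profiles of EDJ length
  against time;
* gestational arithmetic: with a 273-day pregnancy and crown initiation
  between gestational days 91–140, full-term pCFT must fall in
  [133, 182] days, so a pCFT ≤ 120 days (a conservative threshold) flags
  a pre-term birth;
* the statistical battery used for such comparisons (Mann-Whitney with
  min-U convention, Kruskal-Wallis, Levene, ANCOVA interaction,
  summary-statistic t), with tie/continuity conventions pinned down;
* a forward **simulator** of prenatal crown growth (decelerating EER,
  depth-dependent DSR, observer noise, neonatal-line survival logic)
  providing ground truth for estimator-recovery tests;
* an 18-individual reference table of per-tooth growth parameters from
  the Imperial Roman Velia series, packaged as `load_velia_table1()`.

## Worked example

```python
from prenatal_enamel import (
    PcftEstimate, classify_cohort, direct_pcft, fit_origin_robust, predict_pcft,
)
from prenatal_enamel.synthetic_enamel import (
    MeasurementConfig, TruthConfig, simulate_cohort,
)

records, truths = simulate_cohort(18, 12/18, TruthConfig(), MeasurementConfig(), seed=42)
points = [(s.length_um, s.count_days) for r in records for s in r.segments]
model = fit_origin_robust(points)
print(f"slope  : {model.slope:.4f} days/um  (95% CI {model.ci_low:.4f}-{model.ci_high:.4f})")
print(f"DSR    : {model.implied_dsr_um_day:.2f} um/day   adj R2 {model.adj_r2:.4f}  n={model.n_points}")
est = predict_pcft(model, records[0])
print(f"{records[0].id}: direct {direct_pcft(records[0]):.1f} d, "
      f"regression {est.days:.1f} d, true {truths[0].true_pcft_days:.1f} d")
labels = classify_cohort([PcftEstimate(r.id, 'direct', direct_pcft(r)) for r in records])
print(f"pre-term {labels.n_preterm} / full-term {labels.n_fullterm} "
      f"(true pre-term {sum(t.is_preterm for t in truths)})")
```

prints

```
slope  : 0.2360 days/um  (95% CI 0.2335-0.2385)
DSR    : 4.24 um/day   adj R2 0.9984  n=72
S001: direct 113.6 d, regression 115.1 d, true 113.7 d
pre-term 8 / full-term 10 (true pre-term 12)
```

The fitted slope converts 1 μm of prism into 0.236 days of growth, i.e.
an overall secretion rate of 4.24 μm/day; the regression-predicted pCFT
for the first tooth misses the true value by 1.4 days.  The classifier
finds 8 of the 12 true pre-term individuals: the 120-day threshold is
deliberately conservative (the derived full-term bound is 133 days), so
late pre-term births with long prenatal enamel records are not flagged.

A command-line front end wraps the same pipeline
(`prenatal-enamel simulate | validate | fit | estimate | rates |
classify | report`); every output directory receives a `provenance.json`
with the config hash and seed.

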