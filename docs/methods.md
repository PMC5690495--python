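# Methods

## The exposure-index scale

All arithmetic rests on the logarithmic exposure index
`EI = 1000·log10(X/X0) + 2000` with reference exposure `X0 = 1.0 mR`
(8.7 µGy air kerma for the reference beam). Consequences used throughout:
an EI difference of Δ multiplies detector exposure by `10^(Δ/1000)`, so
+300 EI ≈ ×1.995, −200 EI ≈ −36.9 %, −400 EI ≈ −60.2 %. Presentation EIs are
rounded to the nearest integer, halves away from zero, matching how vendors
display the value; percent changes quoted in prose are rounded to the
nearest integer percent while raw fractions are kept internally.

One documented inconsistency in common practice: a nominal incident air
kerma of 2.5 µGy is often quoted as "target EI 1450", but through the
formula 2.5 µGy = 0.2874 mR gives EI 1458.4 → 1458. `eiqc` always computes
from the formula and leaves the nominal value to the caller.

## Acceptance testing

**EI display accuracy.** The chamber sits at the field periphery at the
source-to-chamber distance (SCD); its reading is referred to the detector
plane by the inverse-square factor `(SCD/SID)²` and the center-to-periphery
beam-profile ratio, then converted to a *calculated EI*. Percent error is
`(displayed − calculated_unrounded)/calculated_unrounded × 100`; the
integer *deviation* column uses the rounded calculated EI. A row passes at
`|percent error| ≤ 10 %` (inclusive), the detector passes when all rows do.
This convention reproduces the reference acceptance sheet's derived columns
from its inputs; a few printed cells disagree in the last digit
(2.8 % → 2.74 %, 3.1 % → 3.05 %, 1.669 mR → 1.670 mR), consistent with
upstream rounding of the chamber readings, and the tests carry matching
one-least-digit tolerances for exactly those cells.

**Phototimer (AEC) calibration.** Displayed EI over a Lucite ladder
(5–20 cm, 50–130 kVp) is compared to the institutional target; the
acceptance band is target ± 150 EI (inclusive), reflecting achievable AEC
performance across kVp. The manufacturer's ideal ± 20 band (≈ 5 % in
exposure) is reported as an informational flag only, never as pass/fail.
Initial-vs-final recalibration runs are paired by (phantom thickness, kVp)
and summarized by the per-station and mean displayed-EI shift.

## Record ingest

The vendor statistics export is undocumented and varies, so reading goes
through a dialect (delimiter, header map, date convention). Validation is
per-row: a row with an unparseable timestamp or EI is dropped, logged with
its file row number, and counted in provenance; missing mandatory columns
are fatal. EI values outside [0, 3500] are *flagged suspect but kept* — the
scale has no formal bound and outliers are exactly what QC wants to see.
Reject information stays on the record; every distribution statistic
downstream uses accepted records only, while reject rates are computed
separately. Timestamps are timezone-naive local time and months are
calendar months.

## Distribution statistics

Moment estimators follow the spreadsheet conventions of routine physics QC
so results are comparable with reviews done in Excel-like tools: sample SD
with n−1; adjusted Fisher–Pearson skewness `n/((n−1)(n−2))·Σz³`; excess
kurtosis `n(n+1)/((n−1)(n−2)(n−3))·Σz⁴ − 3(n−1)²/((n−2)(n−3))`. Estimators
below their minimum sample size (or with zero SD) are reported absent
rather than NaN. Histograms are unit-area densities over [500, 2600] with a
default bin width of 50 EI points (width is always explicit in outputs, and
a coarser 150-point binning is available through the same parameter);
out-of-range values are clipped into the end bins and counted, never
silently dropped. `fraction_in_range` uses inclusive endpoints on both
sides. Monthly tracking series default to the median (robust against
technique subpopulations); the mean is available because conventions differ
between dataset-level and monthly review.

## Mixture decomposition

The EI distribution of a unit with a technique history is modeled as a 1-D
Gaussian mixture; fitted component means are attributed to known
calibration targets (current AEC 1400, legacy DR 1600, CR-era 1800 by
default). Design choices:

- **Deterministic EM.** Initialization at the k midpoint sample quantiles
  `(2i+1)/(2k)` (chosen over k evenly spaced extreme quantiles to avoid
  seeding components on sample minima/maxima), shared initial SD of sample
  SD / k, equal weights. Runs are reproducible without a seed; an optional
  seeded multi-start mode perturbs the initial means as a robustness check.
- **Convergence** at relative log-likelihood change < 1e−8 or 500
  iterations; the log-likelihood is asserted nondecreasing every iteration.
- **SD floor of 10 EI points**: EI is integer-quantized, so narrower
  components are quantization artifacts; the floor also prevents the
  classical likelihood singularities of unconstrained 1-D EM.
- **Model order by BIC**, `−2·logL + (3k−1)·ln n`, over k = 1..3 by
  default. Visual histogram reading motivates the decomposition but is not
  a selection criterion.
- **Attribution**: nearest ledger target within 100 EI points (half the
  spacing of the historical targets); distance ties resolve to the lower
  target; anything farther is "unattributed". Attribution depends only on
  component means, hence is invariant to component ordering.

The fitted fraction of a component times the sample size gives the implied
event count; counts over components conserve n up to k−1 rounding.

## Compliance rules

A `TargetPolicy` holds the target EI and two inclusive bands: dataset-level
target ± 150 (the accuracy of a phototimer recalibration — a practice
change is "effective" if the dataset statistic lands inside) and monthly
target ± 300 (twice the dataset variability, tolerated because monthly
per-protocol samples are small). The dataset rule uses the mean and the
monthly rule the median by default — written conventions and evaluated
tables genuinely differ on this point, so both are policy fields.
Intervention effects compare the median of monthly medians before vs after
(changepoint month inclusive on the "after" side) and convert the EI drop
to a relative exposure change; reports print one decimal on the percent
while prose traditionally rounds to the nearest ten.

The report bundle is deterministic for a given dataset and configuration:
per unit, a protocol table (n, median, SD, share of accepted images),
reject rates, fraction of accepted EIs inside the monthly band, tracking
series with per-month findings, histograms, and — for protocols flagged
out-of-range with at least 100 accepted images — a BIC-selected mixture
decomposition with target attribution.

## Synthetic data

The generator emulates the data-generating situation the analysis assumes:
per unit/protocol/month, events are drawn from a configured Gaussian
mixture of technique subpopulations, rounded to integer EI (half away from
zero) and then clipped to [0, 3500] — rounding before clipping is fixed and
affects tail counts. Timestamps are uniform within the month (no intra-month
structure is modeled), technologists are drawn from a weighted roster, and
rejects are independent Bernoulli draws at a configured probability
(default 0.08, a typical retake rate). Changepoints swap a protocol's
component list from a given month onward, modeling recalibrations and
behavioral interventions. Everything is driven by one seeded numpy
generator with fixed iteration order, so output is byte-identical across
runs at a fixed seed, and the `GenerationManifest` records the exact
per-cell, per-component counts and parameters — the manifest, not any
published summary table, is the oracle for downstream tests.

Built-in scenarios model a two-department institution (A/B) with one
integrated and one retrofit unit each (A1/A2/B1/B2), abdomen and chest
protocols, and two review windows: Jan–Nov 2014 (retrofit target era 1600)
and Dec 2014–May 2015 (target 1400 everywhere). Window volumes equal the
published per-cell image counts (e.g. 1,822 abdomen images on A1 in the
2015 window; 5,810 chest images on A2), spread over months as evenly as
integer division allows. Component means sit at the narrated technique
targets (e.g. A2's 2015 chest mixture is 0.92·N(1800, 180²) +
0.08·N(1250, 80²)); the weights are plausible reconstructions, since the
underlying subpopulation weights were never published. Consequently the
published skewness/kurtosis values are *not* reproduced by construction,
and tests assert fidelity to the manifest, not to those moments.

What passing tests show — and don't. The generator produces exact Gaussian
mixtures with independent events; real EI streams have serial correlation
(shared patients, shifts), patient-size-driven heteroscedasticity, and
heavier tails. Pipeline correctness (ingest, statistics, mixture recovery,
rules, report assembly) transfers to real data; the specific component
shapes do not.

## Problem sizes and numerical notes

Test and acceptance workloads are sized for a laptop-class single core: EM
parameter-recovery checks use 20 replicates of n = 4,000 two-component
samples; the end-to-end pipeline check simulates 4 units × 2 protocols ×
18 months at ~120 exposures per cell (≈ 17k records) with a recalibration
changepoint, and validates every compliance finding against the manifest.
Degenerate inputs are rejected explicitly: EI of a nonpositive exposure,
mixtures of all-equal samples, empty summary inputs, unmatched calibration
stations, changepoints outside the scenario window.
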