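# Methods

This note records the models, conventions and numerical choices behind
`greylung`, and what the synthetic cohort does and does not establish.

## Greyscale quantification

Q-LUS_MGV is the arithmetic mean of the pixel grey values inside the
pleural ROI of an 8-bit frame (sum of grey values divided by pixel count),
kept at full floating precision internally; CSV output is rounded to three
decimals for reporting only. 16-bit input is mapped to 8 bits by
`floor(v/256)` (a bit shift) — the common acquisition-software dialect — with
a linear range-rescale mode available for software that does not fill the
16-bit scale.

ΔQ-LUS_MGV subtracts the mean grey value of the frame acquired at
0 cm H₂O on the **inflation** limb, where the manoeuvre starts. If a
deflation series returns to 0 cm H₂O, that frame is deliberately *not* the
baseline: the deflation-end lung retains volume (hysteresis), so using it
would shift every delta by the hysteresis offset.

## ROI geometry and detection

The ROI is a rectangular band: superior margin at the pleural line,
lateral margins at the rib shadows, inferior margin `depth_mm` (default
1.0 mm) below the pleural line. At the default isotropic spacing of
0.02 mm/px this is exactly 50 rows. Conventions are fixed package-wide to
avoid off-by-one drift: rows are 0-based half-open
(`[pleural_row, pleural_row + depth_px)`), columns 0-based inclusive
(`[left_col, right_col]`). The bright pleural line itself lies **inside**
the band — its brightness carries part of the aeration signal; this is an
interpretive choice, since a hand-traced ROI could equally start one row
below the line.

Automatic detection:

* **Pleural line** — argmax of the row-mean intensity profile after light
  vertical smoothing (3-row uniform filter), refined to the raw-profile
  peak within the smoothing window (the line sits on an asymmetric
  background — dark chest wall above, bright band below — so the smoothed
  argmax alone can land one row deep). Ties resolve to the shallower row.
  A zero-variance image raises a detection error.
* **Rib shadows** — column means over the rows at and below the pleural
  line; a column is shadow when below `0.35 ×` the whole-image median. The
  threshold is relative to the image median rather than absolute so that a
  global gain change rescales signal and threshold together, leaving the
  segmentation invariant. The maximal shadow run touching each flank is
  excised; a flank without shadow falls back to the image edge with a
  warning; an image whose median is zero (or whose columns are all shadow)
  raises a detection error.
* A band that would run off the image bottom is clipped silently up to 10%
  of its rows and is a geometry error beyond that.

Manual ROIs are imported from JSON, either as the four band bounds or as a
traced polygon rasterised to a mask; a bounds import is bit-identical to
the automatically built band with the same numbers.

## PV modelling

**Venegas sigmoid.** V(P) = a + b/(1 + exp((c − P)/d)), with a the lower
asymptote (signal units), b the span (upper asymptote a + b), c the
inflection pressure and d > 0 the width (both cm H₂O). The sign convention
makes V strictly increasing in P for b > 0. Fitting is bounded
trust-region least squares (b, d > 0) with the data-driven start
(a₀ = min, b₀ = range, c₀ = pressure of the value nearest midrange,
d₀ = pressure span / 8) plus four seeded jittered restarts; the lowest
residual sum of squares wins. Multistart guards against the sigmoid's
flat-tail local minima; tolerances are set to machine level (1e-14) so
noiseless data refit to ~1e-6 relative error. Standard errors come from
the Gauss–Newton covariance s²(JᵀJ)⁻¹. Goodness of fit is reported as
adjusted R² with the four-parameter correction,
1 − (1 − R²)(n − 1)/(n − 5), and a two-sided Wald–Wolfowitz runs test on
the residual signs (exact conditional distribution for n ≤ 20 informative
residuals, normal approximation with continuity correction beyond;
residuals below 1e-10 of the largest magnitude count as zero so a perfect
fit yields an undefined rather than a spurious p).

**Model-predicted opening/closing pressures.** The derivative
dV/dP = (b/d)·s(1 − s), s = 1/(1 + exp((c − P)/d)), peaks analytically at
P = c. The implementation takes the argmax on a dense grid over
[0, 35] cm H₂O (default step 0.1) and cross-checks it against c: the grid
keeps the answer inside the physiological range when a fitted c falls
outside it (a boundary warning is emitted and the boundary argmax
returned). The 0.1 cm H₂O grid step is a resolution choice; halving it
changes predicted pressures by at most 0.05 cm H₂O.

**Empirical opening/closing pressures.** The pressure of the point
immediately preceding the largest single-step increase (inflation) or
decrease (deflation) along the acquisition order. Ties break toward the
lower pressure on inflation and the higher on deflation — the conservative
direction for recruitment/derecruitment. A limb whose steps are all zero
is flagged undetectable rather than erroring.

**Hysteresis.** Present when the mean paired deflation-minus-inflation
difference over the pressures common to both limbs is strictly positive —
a descriptive rule, deliberately not a hypothesis test. The trapezoidal
loop area over the matched pressures and a one-sided paired Wilcoxon p are
reported as supporting evidence only. Under this sign rule, exchangeable
noise on identical limbs fires ~50% of the time; that behaviour is
documented and tested, not corrected.

**EIT calibration.** The right-whole impedance channel is mapped to the
super-syringe volume scale by least-squares affine regression. Each
regional channel's share is the slope of its regression on the right-whole
channel: constant per-channel offsets cancel in the slope, the three
regional slopes sum to exactly one (their sum is the slope of a channel
differing from right-whole by a constant), and an affine record is
inverted exactly. Regional calibrated volume is share × calibrated whole
volume, so the regions conserve the whole by construction.

## Agreement statistics

* **Spearman rho** with average ranks; p from the t approximation. The CI
  is a seeded percentile bootstrap (default 2000 resamples) — chosen as the
  default because the greyscale data the statistic is used on are skewed
  and no distributional form is assumed; a Fisher-z interval with the
  Fieller–Hartley–Pearson variance 1.06/(n − 3) is available behind a
  flag. Strength classes on |rho| with closed lower bounds: ≥0.70 strong,
  ≥0.50 moderate, ≥0.30 fair, otherwise weak.
* **Friedman** chi-square with row-wise average ranks and the standard tie
  correction, implemented directly so that k = 2 conditions and fully tied
  blocks (statistic 0, p = 1) are handled; it matches
  `scipy.stats.friedmanchisquare` on tie-free input.
* **Wilcoxon signed-rank** pairs with zeros dropped, exact null
  distribution for ≤ 25 informative pairs and the normal approximation
  beyond; Bonferroni adjustment `min(1, p·m)` with the family size m
  defaulting to the number of pairs actually tested (configurable to match
  any published family).
* **ICC(2,1)** — two-way random effects, absolute agreement, single rater —
  from the ANOVA mean squares, (MSR − MSE)/(MSR + (k−1)MSE + k(MSC −
  MSE)/n), with the McGraw–Wong F-based confidence interval
  (Satterthwaite degrees of freedom). This form is used because each
  observer scores every image exactly once; the label is emitted with every
  result so outputs are self-describing. Rater variance components below
  1e-12 of MSR are treated as zero, so duplicated columns give exactly 1
  with a degenerate interval.

Significance is fixed at 0.05 throughout.

## Synthetic cohort generator

The generator emulates a preterm-lamb PV-mapping experiment: each lamb
carries a hysteretic pair of Venegas curves, a regional volume partition,
an EIT-like impedance record, and rendered ultrasound stills.

* **Schedule** — inflation 0, 5, 10, 15, 20, 25, 30, 35 cm H₂O; deflation
  30, 25, 20, 15, 10 (13 frames per lamb, configurable). The exact
  experimental increments are not fixed by the protocol being emulated;
  this grid spans the manoeuvre symmetrically and yields 260 frames per
  20-lamb imaging group.
* **PV truth** — a ~ U(0, 2) ml/kg; upper asymptote a + b drawn
  N(24, 3) ml/kg for dependent-imaged and N(22, 3) for
  non-dependent-imaged lambs (the scale of a surfactant-deficient preterm
  lamb at total lung capacity); c ~ U(18, 24) cm H₂O, d ~ U(2, 4) cm H₂O.
  The deflation limb reuses the inflation parameters with c reduced by
  Δc ~ U(4, 10) cm H₂O. Because the sigmoid is increasing in P and
  decreasing in c, this left shift guarantees deflation ≥ inflation at
  every pressure — hysteresis holds by construction, and the deflation
  inflection (closing pressure) sits below the inflation inflection
  (opening pressure), as physiology requires.
* **Regional partition** — right lung fraction U(0.40, 0.50) of total;
  ventral/central/dorsal weights drawn U(0.8, 1.2) and normalised to sum
  to one. Regions are fixed fractions per lamb, so regional curves are
  scaled copies of the total curve.
* **Echogenicity** — the 1-mm sub-pleural band's expected mean intensity is
  `clip(echo_baseline + echo_gain × regional volume, 0, 255)` with
  baseline U(35, 45) AU and gain U(8, 15) AU/(ml/kg): affine because the
  emulated finding is a monotone association, not a known transfer
  function (a saturating variant would only compress the upper range).
  The imaged region follows the probe position: dependent imaging sees the
  central EIT region, non-dependent the ventral. The pleural-line row is
  drawn 40 AU brighter than the band target and the 49 rows beneath are
  dimmed so the 50-row band mean hits the target exactly before
  quantisation; dark rib-shadow bands (about 3 AU) occupy both flanks
  below the pleural line. Additive Gaussian noise with per-lamb sd
  U(1, 2) AU stands in for speckle. After ROI averaging over thousands of
  pixels this pixel noise contributes only ~0.03 AU to a frame's mean, so
  the dominant variability in cohort statistics is between-lamb parameter
  heterogeneity, as in a real cohort.
* **Observers** — observer A is the computed ROI mean; observer B adds
  independent N(0, 2 AU) reading noise, emulating a second reader
  re-measuring the same image.
* **Determinism** — per-lamb seeds spawn from the master seed
  (`SeedSequence`), per-frame generators from the lamb seed and frame
  index; a cohort is bit-for-bit reproducible, and frame geometry (pleural
  depth, shadow widths) is fixed per lamb across the manoeuvre as probe
  position would be.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: no ultrasound physics (speckle is additive
Gaussian, not multiplicative Rayleigh; no attenuation, A-lines or
reverberation), no probe-angle or contact variability, no heterogeneous or
regionally inconsistent lung disease, no drift in machine settings, and
regional volumes that are exact fixed fractions of the total. Agreement
statistics on synthetic cohorts are therefore optimistic upper bounds —
correlations near 0.9–1.0 where heterogeneous animal data yield 0.3–0.6 —
and validate the *machinery* (estimators, detection rules, calibration
algebra), not field performance.

## Problem sizes

Default analysis runs use 40 lambs × 13 frames (520 stills, 160 × 200 px);
recovery experiments use 200 replicates and null-calibration checks 400–500
simulations. These sizes give Monte-Carlo standard errors comfortably
below the tolerances asserted (e.g. binomial sd ≈ 2.5% on a 50% null rate
at n = 400) while keeping a full run under a minute on one CPU.

## Known limitations

* The empirical step rule reports grid pressures, so its resolution is the
  schedule increment (5 cm H₂O by default); a true inflection near a grid
  point can legitimately land in either adjacent step.
* Pooled fits concatenate lambs without per-lamb normalisation of the
  greyscale gain, so between-lamb gain spread deflates pooled adjusted R²
  relative to per-lamb fits; this mirrors pooling raw deltas across
  animals.
* A deflation inflection below the lowest deflation pressure (possible
  when the drawn Δc is large) is only partially observable from the
  schedule; the empirical closing pressure then saturates at the lowest
  step, which is the correct behaviour of the rule, not a bug.
* ICC assumes homoscedastic rater noise; the simulated observer B is
  exactly that, so the ICC acceptance bound says nothing about real-reader
  heteroscedasticity.
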