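# Methods

`ultradce` analyzes the early enhancement phase of ultrafast dynamic
contrast-enhanced (DCE) MRI of the prostate. This note records the
models it implements, the numerical and design choices that were
genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Signal model and preprocessing

Signal is converted to contrast-agent concentration with the
linearized relation

    C(t) = R (S(t) - S0) / S0,        R = 1 / (r1 T10),

where `S0` is the per-voxel baseline computed over frames 2 through
the last pre-arrival frame (the first two frames are excluded because
the gradient-echo signal has not reached steady state). Without a T1
map, `R = 1` by default, which assumes identical native T1 in lesions
and healthy tissue; concentrations are then unitless relative
enhancements and every fitted amplitude-like parameter inherits this
arbitrary scale. Voxels with nonpositive baseline are flagged invalid
rather than raising. Negative concentrations from noise are kept:
clipping at zero would bias fits near baseline.

The arterial input function (AIF) is the mean concentration curve over
an artery ROI, used without amplitude correction, rescaling or
dispersion correction — so `vp`, `PS` and `Fp` are proportional to an
unknown AIF scale factor, which is why the credible range for `vp`
extends to 10 rather than the physical limit of 1.

**Bolus arrival.** No standard reference rule exists for arrival
detection, so the package uses a conventional threshold heuristic: the
first frame exceeding the running-baseline mean by 5 baseline SDs,
*sustained for two consecutive frames*, with at least 3 baseline
frames required before a trigger counts and the SD floored at 1e-6 of
the curve's range. The sustain requirement and minimum baseline exist
because with one or two baseline frames the SD estimate is degenerate
and ordinary noise would trigger almost immediately; with them, the
detector recovers a known arrival frame to within one frame at SNR 50.
If the threshold never fires the detector falls back to the start of
the steepest global upslope.

All model fitting is restricted to a 2-minute window from the detected
arrival (71 frames at 1.695 s per dynamic), where back-flux of tracer
into plasma is negligible and wash-out does not distort uptake fitting.

## Two-compartment uptake model

The 2CU model treats each voxel as a plasma compartment with flow
`Fp` (per minute) feeding a unidirectional leak `PS` (per minute) into
the extravascular extracellular space. Its impulse response is
biexponential,

    I(tau) = alpha_plus + alpha_minus exp(-beta_minus tau),  tau >= 0,

and the tissue curve is `I * AIF` (causal convolution). The
biexponential and physiological parameterizations are related by

    Fp = alpha_plus + alpha_minus,   E = alpha_plus / Fp,
    PS = Fp E / (1 - E),             vp = (Fp + PS) / beta_minus,

equivalently `I(tau) = Fp [E + (1-E) exp(-tau/MTTp)]` with
`MTTp = vp/(PS+Fp) = 1/beta_minus`. Derived quantities: capillary
transit time `Tc = vp/Fp`, extraction fraction `E = PS/(PS+Fp)`, and
`Ktrans = E Fp` (identically `alpha_plus`). The mapping is validated
in both directions against the standard worked pair
(0.2, 0.2, 4) <-> (Fp, PS, vp) = (0.4, 0.4, 0.2) and by checking that
the two parameterizations generate identical forward curves on
arbitrary AIFs.

**Convolution.** The forward model evaluates `I * AIF` treating the
AIF as piecewise linear between frames: the constant term of `I`
integrates by the (then exact) trapezoidal rule, and the exponential
term by an exact recursive closed form (`y[k] = e^{-beta dt} y[k-1] +`
closed-form segment integral). A sampled trapezoidal convolution was
measured at ~0.3% error against a 100x-oversampled quadrature at
`beta_minus = 8/min` on the 1.695 s grid; the exact-kernel form is at
3e-7 and its cost is the same. A fitted bolus delay `t0` (off by
default; both tissue window and AIF are re-origined at the detected
arrival) shifts the zero-delay solution by linear interpolation.

**Fitting.** Per-voxel bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the
biexponential parameters from the fixed start (0.2, 0.2, 4). The
optimizer uses loose positivity bounds (`alpha± in [0, 20]`,
`beta- in (0, 100]`); the physiologically credible ranges are applied
*afterwards* as validity masks. Post-hoc masking rather than optimizer
constraints is deliberate: it reproduces the observable situation in
which an ROI can contain *no* voxel with credible `PS` while remaining
usable for the other parameters, which constrained optimization would
make impossible. A whole ROI losing one parameter then simply drops
out of that parameter's analyses. An optional config-selectable mode
can constrain the optimizer instead; a seeded 3-start multistart is
likewise available but off by default, since the single printed start
converges on all tested phantoms.

Credible ranges: `vp` [0,10], `PS` (0,10], `Fp` [0,10], `MTTp` and
`Tc` [0,5) min, `E` [0,1], `Ktrans` [0,10] /min, exponential rate
`alpha` (0,1] per dynamic, sigmoid `A1-T0` and `A2` (0,100] dynamics.
Amplitudes, arrival times and TTP are unconstrained.

## Empirical enhancement models

Two amplitude/shape models are fitted per voxel on the same window,
with time measured in dynamics (frames):

* exponential uptake `C(t) = A (1 - exp(-alpha (t - t0)))` for
  `t >= t0`, zero before;
* sigmoidal uptake `C(t) = A0 Phi((t - A1)/A2)` with `Phi` the
  standard normal CDF.

The sigmoid is written with the `1/A2` normalization inside the
Gaussian integral so that `A0` is the plateau amplitude and `A2` a
width in time units — the only reading under which "amplitude" and
"slope" keep their meanings; `A1` is reported relative to the arrival
reference as `A1 - T0`.

Weights are binary and form a contiguous prefix: 1 over the uptake
phase, 0 afterwards, so wash-out cannot distort the uptake fit. The
default cutoff is the later of 120 s and the peak of enhancement
(`max120_peak`); pure `fixed_120s` and `to_peak` policies are
selectable. A per-voxel cutoff chosen adaptively by the optimizer
itself is not reproducible from any published description and is
approximated by `to_peak`.

Starting estimates come from the curve itself: the plateau estimate is
the mean of the last 10% of weighted frames; the exponential rate from
the half-amplitude crossing (`alpha = ln 2 / t_half`); the sigmoid
center from the half-amplitude crossing and the width from the
10–90% rise time divided by 2.563 (the 10–90 span of a unit normal
CDF). Flat curves return a degenerate-start flag and defaults.

Time to peak (TTP) is the argmax frame of the windowed curve, in
dynamics after arrival, ties broken to the earliest maximum; it is
invariant under positive affine rescaling of the curve.

## ROI summaries

Parameter maps are masked *before* averaging: an ROI summary is the
mean and sample SD (n−1 denominator) over voxels that are inside the
ROI and valid in the map. Empty summaries (no credible voxels) are
dropped from the cohort table with a logged reason, leaving the ROI's
other parameters untouched. The ROI mean is the unit of analysis
downstream; voxelwise statistics are out of scope. Transition and
central zones are merged into a single "TZ" level.

## Cohort statistics

Four analyses per parameter, on ROI means:

1. **Zone t-test** — normal-appearing PZ vs TZ, Welch by default
   (n = 29 vs 6 with unequal variances is exactly where Welch is
   preferable; Student's is a config flag). At these group sizes
   Welch's true size is ~0.055 at nominal 0.05 — slightly
   anticonservative but within the binomial calibration band.
2. **Two-way ANOVA** — all ROIs, main effects of zone (2 levels) and
   PI-RADS category (4 levels, normal-appearing = category 1), no
   interaction, Type II sums of squares. The design is heavily
   unbalanced; Type II yields exactly one p-value per factor and
   coincides with sequential SS on balanced data (tested).
3. **Biopsy t-test** — grade-group negative vs positive (GG >= 1),
   peripheral-zone lesions only.
4. **One-way GG ANOVA** — five levels over the peripheral zone, with
   normal-appearing ROIs folded into the GG-negative level.

Parameters significant in an ANOVA get Tukey HSD (Tukey–Kramer)
post-hoc pairwise comparisons. One Benjamini–Hochberg family at
q = 0.05 spans the 33 ANOVA p-values (11 parameters × 2 two-way
factors + 11 one-way tests); the t-test families are reported
uncorrected, and a config flag can pull them into the family.
Zero-variance degenerate groups return p = 1 with a flag instead of
failing the run. The amplitude parameters `A`, `t0`, `A0` are computed
but excluded from the analyses (negligible spatial contrast).

Implementation rests on `statsmodels` (OLS/anova_lm, pairwise Tukey,
BH step-up) and `scipy.stats`; the test suite checks them against
hand-rolled oracles (brute-force step-up enumeration, pooled t
equivalence at k = 2, Type I/II equivalence on balanced designs).

## Synthetic data

The generator emulates the acquisition and cohort conditions end to
end: 1.695 s per dynamic, 150 dynamics, gamma-variate first-pass AIF
(`a (t-ta)^b exp(-(t-ta)/c)`, arrival 25 s, peak 5 in relative
enhancement units, optional recirculation), tissue curves from the 2CU
or empirical forward models, Gaussian signal noise specified relative
to baseline (Rician optional — at prostate DCE SNR the difference is
negligible and enters only far below SNR ~5), and a cohort of 25
patients with 35 lesions (29 PZ / 6 TZ; PI-RADS 3/4/5 = 4/21/10;
GG neg/1/2/3/4 = 11/6/9/5/4) each paired with a normal-appearing ROI.

The fast-path cohort generator draws ROI means directly from a
location-shift model: baseline + per-level shift (in units of the
within-group SD, default 30% of baseline) + Gaussian noise. Default
baselines are plausible normal-PZ magnitudes (e.g. Fp 1.363/min,
alpha 0.0723/dynamic); default effects put monotone shifts on Fp,
MTTp, Tc, E, alpha, A1-T0, A2 and TTP (1 SD per PI-RADS level, 0.8 SD
per GG level, signs chosen so flow/extraction rise and transit/rise
times shorten with grade) and none on vp, PS, Ktrans.

What the generator does **not** emulate: anatomy and partial-volume
structure, motion, B1/T1 physics and nonlinear signal saturation,
AIF dispersion between artery and tissue, spatial noise correlation
from undersampled reconstruction, and correlation between lesions of
one patient (ROIs are treated as independent, as the analyses assume).
Passing tests therefore demonstrate correctness of the estimators and
analyses under their own assumptions — not robustness to these real-
world effects.

## Problem sizes and tolerances

Simulation studies use sizes chosen to make Monte-Carlo error small
relative to the margins being tested: 200 replicates for median-bias
checks at SNR 20 (median bias of all checked parameters < 5%; the
200-replicate median of the heavier-tailed `Tc` error distribution
fluctuates by a few percentage points between streams, while its
2000-replicate value is ≈ −2%), 100 replicates per SNR for the
RMSE-vs-SNR monotonicity sweep, 1000 cohort replicates for type-I
calibration (binomial 95% band 0.0365–0.0635), and 300 cohort
replicates for effect selectivity. Seeds derive from
`numpy.random.SeedSequence` spawning so every replicate has an
independent stream. Optimizer tolerances are `xtol = ftol = gtol =
1e-12`; "noiseless recovery" means relative error below 1e-4.

## Known limitations

* Concentration linearization ignores T1 and saturation effects; all
  amplitudes share the unknown AIF scale.
* The arrival detector is a heuristic stand-in for expert annotation;
  its two-frame sustain rule delays detection by one frame on
  extremely slow bolus profiles.
* The 2-minute window truncates wash-out information, which limits
  `PS` identifiability by design (mirrored in its weak selectivity).
* Multiple lesions per patient are treated as independent
  observations; a mixed-effects treatment is out of scope.
* The `t0`-fitting mode interpolates the zero-delay solution and is
  approximate at sub-frame delays.
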