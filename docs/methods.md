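# Methods

This note documents the models and procedures implemented in `boldwaves`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions a user comparing
against another toolchain should know about.

## Signals

Per-run processing order is **band-pass → z-normalise → average**. The
band is 0.01–0.1 Hz (the infra-slow band in which global BOLD–CSF
coupling and cortical propagation are observed), realised as an order-2
Butterworth applied forward and backward (`scipy.signal.sosfiltfilt`).
The zero-phase realisation matters: a causal filter would shift every
signal by a frequency-dependent delay and bias the lag structure that the
coupling analysis reads out. Runs must span at least three cycles of the
low cutoff (≥ 300 s at 0.01 Hz); the standard 478-frame, TR = 0.8 s run
(382 s) qualifies. Filter edge transients at an 0.01 Hz cutoff are long;
they affect the first/last few tens of seconds of a run and are accepted
rather than trimmed, matching common practice.

Z-normalisation is per unit (voxel/vertex): subtract the temporal mean,
divide by the temporal SD. Zero-variance units are set to zero and
flagged rather than aborting the run.

* **gBOLD** — unweighted mean across gray-matter voxels (volume) or all
  cortical vertices (surface). Volume-based gBOLD is used for coupling
  and amplitude; the surface mean drives the wave analysis.
* **CSF inflow** — mean over a supplied bottom-slice ROI, then z-scored.
  Whether the CSF signal is normalised is immaterial for the Pearson
  cross-correlation; we normalise for output readability.
* **gBOLD amplitude** — the temporal SD of the per-run gBOLD signal,
  averaged over a subject's runs. Because gBOLD is a mean of unit-variance
  time courses, its SD directly measures global synchrony: perfectly
  incoherent activity gives ≈ 0, perfectly coherent activity gives ≈ 1.
  Other summaries (envelope, peak measures) were considered; the SD was
  chosen as the simplest statistic monotone in planted global-event
  strength, and the package's tests verify that monotonicity.

## Coupling

`xcorr(g, c)` computes, for every lag τ on the TR grid spanning ±16 s
(±20 frames at TR 0.8 s), the Pearson correlation over the truncated
overlap of the two series, with means and SDs recomputed per lag — not an
FFT correlation, which would wrap around or assume stationarity of the
global mean.

**Lag-sign convention.** `values[τ] = corr(g(t), c(t + τ))`: positive τ
pairs the CSF sample τ seconds *later* with the current gBOLD sample, so
a negative value at positive τ means CSF inflow follows global BOLD
deactivation. Under this convention a CSF signal generated as a delayed
negative copy of gBOLD produces its negative CCF trough at the positive
generative lag. Toolchains with the opposite convention will see the
mirror image; the convention is asserted by a property test
(`xcorr(a,b)[τ] = xcorr(b,a)[−τ]`).

Subject-level coupling averages the per-run CCFs pointwise and reads the
+3.2 s value; since the readout is linear, this equals the mean of the
per-run +3.2 s values, and both are retained. The coupling lag is a
configuration constant, not fitted per subject: fitting the trough per
subject would bias the group comparison through lag-selection noise.
There is no interpolation off the lag grid — +3.2 s is exactly 4 frames
at TR 0.8 s, and requesting an off-grid lag is an error.

Parcel-level maps use DKT-68 parcel means: *gBOLD presence* is each
parcel's zero-lag correlation with the whole-surface mean; *rBOLD–CSF
coupling* is each parcel's CCF value at the same fixed +3.2 s lag.

## Waves

1. **Binning.** Vertices are sorted by principal-gradient score and cut
   into 70 contiguous bins of near-equal count ("evenly divided" is read
   as equal *count*, not equal PG range — equal-count bins give every bin
   the same averaging noise). Ties are broken by vertex index. When the
   vertex count is not divisible by 70, the ±1 occupancy remainders are
   laid out palindromically, so binning commutes exactly with a sign flip
   of the PG map; direction equivariance of the classifier (negating the
   PG swaps bottom-up and top-down labels with |r| and p unchanged) then
   holds exactly, and is tested exactly.
2. **Segmentation.** Troughs are strict local minima of the band-limited
   surface-mean signal (lower than both neighbours; no prominence
   threshold, since the 0.01–0.1 Hz filter already suppresses spurious
   minima). Consecutive troughs delimit half-open segments; data before
   the first and after the last trough are discarded. Each segment's
   global peak is the argmax of the surface mean within it.
3. **Peak timing.** Within a segment, each bin contributes its *largest
   local peak*: among all strict interior local maxima of the bin's
   course inside the window, the one with the greatest value; plateaus
   count once at their earliest frame; segment-edge frames never qualify.
   Bins with no interior local maximum are missing. Delay = (peak frame −
   global peak frame) × TR.
4. **Classification.** Segments with local peaks in fewer than 80% of
   bins (or fewer than 3 usable bins, where the correlation is
   degenerate) are excluded as lacking global involvement; the 80% rule
   is inclusive (56/70 passes, 55/70 does not). Otherwise Pearson's r is
   computed between delay and bin rank along the ascending PG (rank, not
   mean PG score: with equal-count bins the two are monotonically
   equivalent and rank is scale-free), with the standard two-sided
   t-distribution p-value on n = usable bins. `p < 0.01` with `r > 0` /
   `r < 0` labels bottom-up / top-down; `p > 0.05` labels
   no-propagation; the 0.01 ≤ p ≤ 0.05 band is labelled *unclassified*
   and excluded from all counts rather than assigned to either side.
   Note the bins are spatially correlated time series, so the nominal
   t-test is not exactly calibrated at the segment level; the test suite
   measures (rather than assumes) that the false-wave rate under pure
   noise stays within a small multiple of nominal.
5. **Counts and averages.** Subject wave counts are summed over runs; raw
   counts are only compared across subjects when run durations match
   (else counts are normalised to events/minute and flagged). Wave-locked
   averages align bin × time excerpts on each event's global peak over a
   symmetric window, dropping events whose window leaves the run.
   Covariate maps correlate each (bin, time) cell with a subject
   covariate across subjects, after residualising the linear age-at-MRI
   effect from both.

## Head motion

FD is the literal six-parameter sum `Σ|Δp|` per frame transition, with
rotational increments (radians by default, configurable) summed directly
with translations — i.e. no 50-mm-sphere arc-length conversion. The
resulting number has mixed units and is used only as a relative motion
index (mFD = session mean); the convention is kept because it matches the
formula the cohort analyses are defined with. Motion enters the analysis
only as a confound check: mFD is compared between groups, correlated with
the imaging metrics, and the group comparisons are repeated after
residualising mFD out of the metric. Motion parameters are deliberately
*not* regressed out of the BOLD data, to avoid attenuating the global
signal itself.

## Cohort construction and statistics

Subjects are split at menopause age 51 (inclusive on the later side); the
intersection of the two sides' age-at-MRI ranges is computed; subjects
scanned outside that overlap are excluded (this is what decouples
menopause timing from age at scan); the remainder is sorted by
(menopause age, subject id) and cut into equal tertiles — earlier,
intermediate, later — with earlier tertiles receiving the extras when the
count is not divisible by three. The assignment is deterministic and
invariant to input row order. Phenotype rows with a recorded menopause
age later than the scan age are flagged as abnormal and never enter.

All metric comparisons first regress the linear effect of age at MRI out
of the metric (OLS residual on an intercept-plus-age design) across all
included subjects. Group tests are classical pooled-variance two-sample
t-tests; the across-tertile trend ("ordinal regression" on a continuous
metric) is a linear regression on the ordinal group code 1/2/3, with a
configuration switch to use raw menopause age as the predictor instead;
balance checks use one-way ANOVA. Memory analyses drop scores coded 999
or NaN, then correlate age-adjusted wave counts with age-adjusted scores
within the earlier group. The per-cell wave-activation model is an OLS of
activation on (intercept, age, score); a rank-deficient design raises an
error rather than silently dropping a predictor. No multiple-testing
correction is applied anywhere; map cells are thresholded at raw
p < 0.05.

The residualise-then-correlate composition slightly inflates the nominal
null rate of the correlation test (the p-value uses n−2 dof while the
residuals carry n−3); at the cohort sizes involved this is ≲ 1 percentage
point and is left as is, since the composition *is* the procedure being
implemented.

## The synthetic-data generator

The generator emulates the statistical skeleton of the study conditions:
four 478-frame runs at TR 0.8 s per subject; a cohort of 124 phenotype
rows of which 90 survive the overlap exclusion and split into tertiles of
30.

* **Vertex noise** is AR(1) (coefficient 0.4) band-limited to
  0.01–0.1 Hz and rescaled to unit SD — the simplest process with the
  infra-slow autocorrelation that makes naive wave-test calibration
  non-trivial. Full 1/f spectra, physiological (cardiac/respiratory)
  components, and scanner artifacts are not modelled.
* **Global events** are Gaussian bumps (duration 12 s, σ = 3 s) injected
  at ~2 events/min with amplitude 2 noise-SD (SNR 2). A bottom-up event
  delays each vertex's bump centre linearly with its PG rank across an
  8 s propagation span; top-down reverses the ordering; synchronous
  events use a common centre. The default direction mix is
  0.4/0.3/0.3 (bottom-up/top-down/synchronous).
* **CSF** is generated as a lagged (default +3.2 s) negative copy of the
  global signal plus white noise (noise SD = 0.5 × signal SD, SNR 2); a
  target coupling value, when requested, is converted to the equivalent
  gain. A negative-derivative CSF model was considered and rejected as
  the default because only the empirical negative trough at a positive
  lag is being emulated, and the delayed-copy model pins that trough
  directly at the configured lag.
* **Surface scale** is reduced to 2,000 vertices (vs ~59k in real data)
  while keeping 70 bins, so bin-level statistics remain comparable at
  desk-scale runtime. The stand-in PG map is smoothed white noise over
  the vertex index; DKT-style parcels are contiguous blocks of the PG
  ordering. Real cortical geometry, spatial autocorrelation between
  neighbouring vertices, and registration error are not modelled — so
  passing recovery tests demonstrate correctness of the *method*, not
  performance on real cortical data.
* **Phenotypes** are built so the counting flow holds by construction for
  every seed: retained subjects are scanned inside the 52.9–66.5 y
  overlap window (with all four endpoint subjects pinned), the two
  exclusion arms sit below and above it, and menopause never postdates
  the scan. Ages are rounded to 0.1 y after all constraints are applied.
  Planted effects, all configurable and zeroable for null cohorts:
  coupling weakening of 0.15 correlation units between extreme tertiles
  (subject SD 0.08 around a base of −0.6), a 20% amplitude reduction
  (subject CV 10%), an 8-point PSMT deficit in the earlier group, and a
  ρ = 0.5 Gaussian-copula correlation between bottom-up wave count
  (mean 15, SD 4, rounded) and the latent memory factor in the earlier
  group only. About 7% of scores are set missing, alternating between
  the 999 sentinel and NaN to exercise both codes.
* **Tiers.** `tier="none"` generates phenotypes, planted parameters, and
  wave counts only; `tier="signals"` adds per-run global/CSF time courses
  and motion (no vertex matrices); `tier="full"` adds the vertex × frame
  runs. Replicated cohort experiments (lag recovery, power, null
  calibration) run at the signal tier and the count/score tier — a
  full-vertex 90-subject cohort replicated hundreds of times is far
  beyond desk scale — while the wave classifier is exercised at the full
  tier. All randomness descends from one master seed via
  `numpy.random.SeedSequence` spawning, so cohorts are bit-reproducible
  and per-subject streams are independent.

## Validation experiments

`boldwaves.validation` (used by both the test suite and
`scripts/acceptance.py`) measures:

* exact agreement (≤ 1e−12) of the cross-correlation and FD kernels with
  brute-force loops;
* recovery of planted CSF lags (1.6/3.2/4.8 s at SNR 2) by the group-mean
  CCF trough, 100 replicates of 5 subjects × 4 runs;
* planted-wave label recovery over 30 full-tier runs (~350 events), plus
  the exact direction-flip equivariance check;
* the 80% involvement boundary (55/70 vs 56/70);
* the cohort counting flow and its row-order invariance;
* power of the earlier-vs-later coupling t-test under the planted
  0.15-unit weakening (100 signal-tier cohort replicates);
* recovery of the planted ρ = 0.5 count/memory correlation (100
  replicates, earlier-group n ≈ 26 after score exclusion);
* null calibration of the five headline tests on effect-free cohorts
  (600 replicates, keeping the Monte-Carlo SE of each rejection rate
  below one percentage point);
* byte-identical outputs of two pipeline runs with the same seed.

## Known limitations

* Volumetric preprocessing (realignment, smoothing, registration),
  surface reconstruction, ICA denoising, and PG derivation are out of
  scope; masks, surface time series, and the PG map are inputs.
* The wave classifier's segment p-values inherit the bin-correlation
  caveat above; treat per-segment p-values as ranking scores, with
  calibration established empirically per dataset.
* The FD convention (no rotation-to-mm conversion) is not comparable with
  Power-style FD values from other packages.
* The generator's cohort effects are linear-in-group simplifications; it
  makes no attempt at realistic anatomy or physiology (see above), and
  conclusions about real-data performance require real data.
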