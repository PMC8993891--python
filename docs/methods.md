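# Methods

`ecogseq` analyzes event-related intracranial (ECoG) recordings of a trait-
judgment task in which participants answer true/false prompts about
themselves (self-mentalizing), another person (other-mentalizing), or simple
arithmetic (cognitive control), with episodic/semantic/rest filler
conditions. The quantity of interest is high-frequency broadband power
(HFB, 70–180 Hz), a proxy for aggregate local population spiking, and the
scientific claims concern *when* each cortical region activates: visual
cortex first, temporoparietal default-mode regions (TPJ, ATL, PMC) next,
medial prefrontal regions (amPFC, dmPFC, vmPFC) last, with later regions
showing stronger mentalizing specificity, stronger coupling to the
behavioral response, and longer activations for other- than for
self-mentalizing.

## Preprocessing

Fixed order: notch filtering (zero-phase 4th-order band-stops at 57–63,
117–123, 177–183 Hz, with 2 s reflection padding), common average reference
over clinically retained channels, Morlet time-frequency decomposition,
per-band z-scoring, epoching, per-trial baseline correction, band averaging,
gaussian smoothing.

* **Morlet decomposition.** The 5-cycle Morlet filter is applied in the
  frequency domain as a gaussian magnitude response centered at fc with
  σ_f = fc / n_cycles — the exact spectrum of the time-domain wavelet. The
  squared magnitude of the analytic output is band power. Analysis band
  centers default to 4–16 Hz in 1-Hz steps, 19–67 Hz in 3-Hz steps, and
  70–180 Hz in 10-Hz steps; only the twelve 70–180 Hz bands enter the HFB
  average. Per band, power is z-scored over the whole recording (the
  per-run alternative is a config switch; the choice is not consequential
  for the synthetic sessions, which are single-run).
* **Epoching.** Trials span [−200, 5000) ms around stimulus onset
  (half-open windows throughout; 0-based sample indices; 1-ms analysis grid
  at the 1000-Hz default rate). Baseline correction subtracts the per-trial,
  per-band mean over [−200, 0) ms *before* band averaging. Samples at or
  after RT + 200 ms (the next trial's territory) are invalid. A trial is
  dropped only if its valid span does not fit in the recording; an epoch
  that merely extends past the end is clipped.
* **Smoothing.** "Width = 50 ms" is read as total kernel support: a
  gaussian with σ = 50/6 ms truncated at ±25 ms, applied with
  mask-normalization so invalid samples neither contribute nor spread. The
  unsmoothed band-averaged trace is kept alongside for diagnostics.
* **Exclusions.** Trials with epileptic high-frequency oscillations, no
  response, irrelevant button presses, or RT under 400 ms are removed
  (a trial at exactly 400 ms is retained); rest trials leave task analyses.
  Per (site, condition, timepoint) cell, observations more than 3 scaled
  MADs (consistency constant 1.4826) from the cross-trial median are
  invalidated; cells with MAD = 0 or fewer than five trials are skipped.

## Single-trial activation detection

Each valid post-stimulus timepoint is tested against the same trial's
baseline using a ±10 ms sliding window (windows shrink at range edges).
P-values are pooled over timepoints × trials × sites of a participant,
Benjamini–Yekutieli adjusted (valid under arbitrary dependence), thresholded
at p_FDR < 0.05, and significance must persist for 50 consecutive
milliseconds (a 49-ms run is cleared; invalid timepoints break runs).
Positive runs yield five metrics: onset (first significant ms), peak
(earliest argmax of the smoothed trace over significant timepoints), offset
(last significant ms), duration (total significant ms over possibly disjoint
runs), and peak power (trace at the peak). Trials without a significant
activation still get a peak power — the maximum of the smoothed trace over
valid [0, RT] — because the site-classification comparisons include
nonsignificant trials. Deactivation runs are counted but produce no latency
metrics.

**Dependence-aware variance.** Millisecond-resolution band power is strongly
serially dependent (the Morlet filters impose a correlation time of
~10–15 ms, and the 50-ms smoothing more). A two-sample test that counts such
samples as independent collapses: on pure-noise traces it yields p < 0.05 at
~70% of timepoints and p < 1e−4 at ~40%, which no FDR procedure can repair.
The sliding test therefore estimates each site's baseline autocorrelation
function (pooled over trials) and uses it to compute the *actual* null
variance of an n-sample window mean, a_w(n)·σ², with a_w(n) =
(1/n²)·Σ_ij ρ(|i−j|), plus the integrated-correlation-time shrinkage of the
baseline degrees of freedom. The noise variance σ² is pooled across the
site's trial baselines (the tested contrast remains within-trial). With
uncorrelated data the statistic reduces to the classic unequal-variance
comparison; with dependence it keeps the false-positive rate near nominal.
On injected 3-z bursts this detector recovers onsets with ~10 ms median
error and durations within ~14%, with zero activations on null montages.

## Trial-averaged analysis

Because epochs are baseline-corrected per trial, the mixed model with one
dummy per peri-stimulus timepoint and a per-trial random intercept reduces
algebraically to the paired contrast of each timepoint against the trial's
baseline mean: β(t) is the cross-trial mean of the corrected trace, its SE
the cross-trial standard error, the p-value a paired t-test. (The
equivalence is asserted against an explicit MixedLM fit in the test suite;
since the paired estimator is O(n), no time-downsampling is needed.)
BY correction runs across timepoints × sites per condition, the 50-ms rule
applies, and sites are labeled active / deactive / nonresponsive, mixed
polarity resolved by the greatest significant deflection. Time-window
summaries ([0,250), [250,500), [500,750), [750,1000), [1000,2000) ms) use
the per-trial window mean as a paired observation, BY-corrected across
sites × windows. ROI grand averages ([0, 3000] ms) pool per-site paired
estimates with across-site SEs — a two-stage approximation of site- and
participant-level random effects rather than one joint LMEM.

## Site classification

A site is *mentalizing-active* if the collapsed self+other trial-averaged
fit is active. Specificity: mentalizing-specific iff not cognitive-active
AND single-trial peak power (all trials) is significantly higher for
mentalizing than arithmetic by bisquare robust regression (BY across sites,
one family per comparison); coactivation for both tasks is non-specific
regardless of the power comparison, as is a nonsignificant excess.
Selectivity applies to sites active for collapsed mentalizing or either
individual type: both types active → self_greater / other_greater /
non_selective by the sign of a significant self-vs-other power difference;
exactly one type active → self_only/other_only only when the power excess is
also significant in that direction, else non_selective. Self-selective
(self_only + self_greater) vs other-selective counts per ROI are compared
with McNemar's χ² (Yates-corrected, df = 1), with the continuity numerator
clamped at zero so equal counts give χ² = 0.

## ROI-level inference

All metrics enter as single-trial observations from mentalizing-active ROI
sites, after two robust-filter stages: trials with RT > 5000 ms are removed;
then per site and metric, bisquare-regression residuals of the metric on RT
beyond 3 scaled MADs are discarded; the same rule is repeated pooling each
ROI's sites, and a site loses its seat entirely when over 50% of its
observations are flagged. (The residual-on-RT reading of the bivariate
outlier statistic is an interpretation; a coordinatewise robust-Mahalanobis
alternative is available behind `method="mahalanobis"` without endorsement.)

* **Per-ROI models** (one per ROI × metric): companion LMEMs with a
  participant grouping and a site variance component — (i) mentalizing type
  (coded +½ other / −½ self, so the effect reads other-minus-self)
  controlling RT and the visual-dissimilarity covariates; (ii) RT and choice
  (+½ true / −½ false) jointly, controlling VDs.
* **Pairwise ROI contrasts**: per trial, the difference of the two ROIs'
  site-mean metrics, modeled with a participant random intercept and a
  centered-RT covariate; restricted to participants with mentalizing-active
  sites in both ROIs; BY across the 21 unique pairs per metric. The
  construction is exactly antisymmetric.
* **Onset → specificity**: logistic mixed classification (participant
  variance component) of the specificity label on per-site mean onset. The
  covariate is fit in 100-ms units for conditioning and reported per ms
  with OR = exp(b).
* **Second-level models**: per-site RT slopes are extracted as BLUPs from a
  random-slope MixedLM (independent per-site OLS slopes on failure,
  flagged), then regressed on per-site mean onset under participant
  nesting.
* **mPFC offset-to-response gap**: RT − offset modeled on a +½ non-mPFC /
  −½ mPFC indicator (participant nesting); positive means non-mPFC offsets
  precede the response by more.

Mixed-model machinery is statsmodels MixedLM (REML) with a fit-health
ladder: full random structure → independent intercepts → pooled OLS, where a
fit is rejected when an effect lands implausibly far from the pooled OLS
estimate or its SE explodes (boundary degeneracies of small-group REML).
Satterthwaite degrees of freedom are not available in statsmodels, so
p-values use the normal approximation and every estimate records which
route produced it. Logistic mixed models use the binomial mixed GLM fit by
MAP with Laplace observed-information SEs (mean-field VB understates
posterior spread; it remains as a secondary route, with its Monte-Carlo
ELBO seeded for reproducibility), falling back to a fixed-effects GLM and,
under complete separation, to an L2-penalized logit whose SEs come from the
penalized information matrix (flagged in `method`).

## Behavioral models

Choice bias: logistic mixed classification of choosing "true" on trait
valence (+½ positive / −½ negative), mentalizing type (+½ self / −½ other),
and their interaction, with trait and participant variance components — a
positive interaction reads "the positivity bias is stronger for
self-mentalizing". RT: participant-nested LMEM on type, choice, their
interaction, and the VD covariates, with per-cell RT means reported.

## The synthetic-data generator

Voltage is pink background noise (PSD ∝ 1/f², 50 µV rms) plus a 60-Hz line
sinusoid (5 µV) plus per-trial bursts of 70–180 Hz band-limited noise,
spectrally shaped like the background within the band, under a trapezoidal
envelope with 20-ms linear ramps (so true onset/offset are unambiguous).
Every draw derives from a per-(participant, site) stream obtained by hashing
(seed, ids), so adding sites never perturbs existing draws.

* **Study conditions.** Defaults follow the study design where stated:
  16 participants, fs = 1000 Hz, 50/50/80 self/other/cognitive trials per
  participant (plus burst-free episodic/semantic/rest filler at 50/50/72),
  ROI onset means 101/303/316/322/465/466/537 ms for Visual/TPJ/ATL/PMC/
  amPFC/dmPFC/vmPFC, choice-model slopes 0.931 (valence) and 0.326
  (valence × type), and a 400-ms RT floor matching the exclusion rule.
  Values the source statistics do not pin down were chosen once as
  field-realistic: trial-level onset SD 15 ms (visual) / 50–70 ms
  (elsewhere), burst durations growing 500→900 ms along the hierarchy with
  other-mentalizing bursts 150 ms longer, burst amplitude 3 z, 90% per-trial
  activation probability, five sites per ROI plus ten non-ROI sites per
  participant.
* **Behavioral coupling.** A per-trial processing-time factor (SD 400 ms)
  stretches all of a trial's burst durations with loadings rising along the
  hierarchy (0.10 visual → 0.85 vmPFC), and RT = 1050 ms + 1.0 × latest
  burst offset + 150 ms/unit × VD1 + N(0, 150 ms), floored at 400 ms. This
  produces offset-on-RT slopes grading from ~0.1 (visual) to ~0.9 (vmPFC),
  self/other RT differences via burst duration and prompt length, and
  mPFC offsets that run closest to the response.
* **Amplitude calibration.** Because per-band power is z-scored over the
  whole recording and is approximately exponential, a sustained in-burst
  elevation of z = a at burst duty fraction f is only achievable when
  a²·f·(2−f) < 1: the bursts themselves inflate the z denominator. The
  generator solves the per-channel variance-inflation quadratic
  k²(1 − 2m₂ + m₁²) − 2m₁k − 1 = 0 (m₁, m₂ the moments of the
  amplitude-weighted squared-envelope duty pattern) for the carrier gain,
  pre-compensates the (1 − 1/n)² attenuation of common average
  referencing, and flags channels where the target is unattainable
  (`calib_feasible`), then uses the bounded-best gain. Realized in-burst
  HFB means sit within 25% of the target at duty ≲ 5% (amplitude 3) and
  correspondingly higher duty at lower amplitudes.
* **What the generator does not emulate**: epileptiform transients,
  non-stationary background spectra, electrode drift/artifacts, cross-site
  noise correlation beyond the common average, and any biophysical forward
  model. Passing tests therefore certify the *analysis rules* (detection
  calibration, classification logic, model estimands), not robustness to
  every pathology of clinical recordings.

## Validation scales and numerical choices

Tests and the acceptance script run at compact scales: detector recovery
uses 1 participant × 10 burst sites × 50 burst trials (+50 filler, +20
common-average filler electrodes); the ordering study uses 2 participants ×
1 site per ROI × 16 mentalizing trials at amplitude 2 over 20 seeds;
parameter recovery uses 50 seeded replicates of 2–4 participants. Full
study scale is reachable through configuration. Miniature fixtures carry
~16 filler electrodes because with tiny montages the common average
re-injects a visible fraction of every burst into every channel — at
realistic montage sizes the leakage is negligible, and the carrier gains
are pre-compensated for the retained (1 − 1/n)² attenuation.

Numerical conventions: ties at the trace peak break to the earliest
timepoint; bisquare IRLS uses tuning constant 4.685, centered scaled-MAD
scale re-estimated each iteration, tolerance 1e−8, 50 iterations, SEs from
the standard robust covariance and two-tailed p on n − k df; BY adjustment
uses the harmonic factor c(m) with a step-up cummin; all tests are
two-tailed; degenerate inputs (zero-variance samples, MAD = 0 cells,
single-participant groups, complete separation) take documented fallback
paths rather than raising.

## Known limitations

The trial-averaged and grand-average estimators share β estimates with the
joint LMEM formulations but do not estimate a joint covariance across
timepoints; p-values from statsmodels mixed fits use normal approximations
rather than Satterthwaite df; the VB logistic posterior SD is an
approximation to the sampling SE; the "Type controlled for RT" estimand
differs from the generator's direct duration increment whenever RT is
coupled to condition (mediation through the RT covariate), which the
recovery studies avoid by decoupling RT in their designs; and the sliding
detector's autocorrelation correction assumes baseline stationarity within
a session.
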