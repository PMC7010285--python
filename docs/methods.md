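# Methods

`valuedyn` implements, and makes verifiable by simulation, a model-based
analysis of two-phase approach--avoidance (ApAv) decision making: a value
signal that is *linear* in subjective value during offer evaluation, and a
confidence signal that is *quadratic* in subjective value during choice
commitment. This note documents the models, the generative assumptions of
the synthetic-data module, the numerical choices, and the limits of what
the simulations can show.

## Behavioral model

Each trial offers a monetary reward paired with a painful shock, both
expressed in percent-of-maximum units on [0, 100]; the subject accepts
both or rejects both. Choices are modelled per subject with logistic
regression,

    SV = b0 + br * reward + bs * shock,      P(accept) = 1 / (1 + e^-SV),

where `br > 0` and `bs < 0` for preference-consistent subjects and `b0`
captures the baseline approach tendency. From the fitted model each trial
receives:

* **SV** — the linear predictor above;
* **confidence** — `SV^2`, the quadratic extension of value: large when SV
  unambiguously favours one choice, near zero at the decision boundary;
* **signed value** — `v = P(acc) − P(rej) = 2 P(acc) − 1`, a
  range-normalized value in (−1, 1) preserving the sign of SV;
* a **condition label** in {AccCon, AccAmb, RejAmb, RejCon} from a median
  split of SV within accepted and within rejected trials (upper-half
  accepts are confident accepts; upper-half rejects are *ambivalent*
  rejects, because for rejections confidence grows as SV falls).

Median-split ties: trials strictly above/below the class median go to the
upper/lower bin; trials exactly at the median fill whichever bin is behind,
alternating (lower bin first) when level. This is deterministic and keeps
the two bins of each class balanced to within one trial.

Quasi-complete separation (nearly deterministic choices) is flagged when
any coefficient magnitude exceeds 15 per percent-unit or the deviance
collapses below 1e-6. Flagged fits carry no usable magnitudes; the
pipeline excludes such subjects from imaging analyses and reports the
count, mirroring how unusable participants are handled in practice.

## Units

The logistic model operates on percent-of-maximum attributes, so
coefficient scales are per percent-of-maximum; a reward coefficient of
0.2 means 20 log-odds across the full reward range. Any other unit
convention rescales the slopes accordingly.

## Task timing

TR = 0.910 s. Per trial: fixation jitter drawn from {0.91, 1.82, 2.73} s,
offer phase 4.55 s (deliberation, no response), commit phase 2.73 s
(1.82 s response window + 0.91 s feedback). Ten of the 189 offers carry a
9.1 s payout alert after feedback. All durations are TR multiples, so
event onsets are scan-aligned. The 189 offers sit on a near-uniform
stratified grid over the reward x shock plane (14 x 14 cell centres, 7
cells dropped at random, ±30%-of-cell jitter), covering all four quadrants
of the decision space; the default session splits them into six runs
of 31 or 32 trials.

## fMRI designs

**GLM1 (parametric).** Seven task regressors: offer and commit phase
boxcars, SV and confidence modulators on each phase's boxcars, and a
payout nuisance regressor (first 4.55 s of the alert modelled; the rest
stays in baseline). Modulators are z-scored within run (population SD)
over the trials entering the fMRI model, convolved, and then
orthogonalized against their phase baseline plus a constant — which
amounts to mean-centering them and leaves modulator betas interpretable.

**HRF.** A gamma kernel parametrized by its *peak*: mode 6 s, SD 3 s,
truncated at 32 s, unit peak (shape/scale solved from mode and SD).
Convolution runs on a 10x oversampled grid, is scaled by the grid step,
and is read out at frame starts; no slice-timing model. The
peak-at-6-s convention was chosen over the mean-lag-6-s one so that the
kernel maximum lands where the canonical response peaks; both are
configurable through `HRFSpec`.

**GLM2 (categorical).** Eight condition regressors (4 conditions x 2
phases) plus the payout nuisance. The condition columns of a phase sum
exactly to that phase's GLM1 baseline column (partition identity, tested).
Empty conditions yield flagged all-zero columns and contrasts touching
them are refused.

**FIR.** Four regressor groups (offer onset, SV, confidence, payout), each
expanded into 18 per-TR indicator columns from 0 to 15.47 s after onset.
With scan-aligned, non-overlapping responses this is an exact
deconvolution (tested); overlapping windows sum, consistent with model
linearity.

**High-pass filter.** Gaussian-weighted running-line fit (sigma = 50 s)
subtracted from the series with the mean restored, applied identically to
data and design. At the window centre the running line predicts the
Gaussian-smoothed value, so the filter attenuates a sinusoid of period T
by `exp(-2 pi^2 sigma^2 / T^2)` — 0.86 at T = 400 s, 0.29 at 200 s,
essentially 0 below 100 s. This closed form is frozen as the test oracle
for the implemented filter. It is a gentle roll-off; the synthetic drift
(linear + 120-s sinusoid) is handled by the filter plus the constant term.

**Collinearity.** Pairwise SV-confidence correlations are averaged across
runs through Fisher's z of the signed r and squared back (z of R^2 itself
is not a standard transform); VIFs come from regressing each column of
interest on all remaining design columns, median across runs, capped at
1e6 and flagged infinite for rank-deficient designs.

## Estimation and group inference

Run-level GLMs are per-voxel OLS; optional AR(1) prewhitening estimates
each voxel's lag-1 residual autocorrelation and refits after a
Cochrane--Orcutt transform (off by default: the synthetic noise is AR(1)
with rho = 0.3, and OLS effect estimates remain unbiased under serial
correlation — only their SEs are optimistic, which the sign-flip
group inference does not rely on). Run contrasts combine within subject by
inverse-variance fixed effects.

Group inference is a one-sample sign-flip permutation test on subject
effect maps: observed one-sample t per voxel, TFCE enhancement
(E = 0.5, H = 2, 6-connectivity), null distribution of the mask-wise
maximum enhanced statistic over random sign flips, corrected
p = (1 + #{null >= obs}) / (n_perm + 1). The TFCE threshold step is
anchored at the observed peak (dh = max_t / 100) and shared by observed
and null maps. Two-sided tests are two one-sided tests at alpha/2. The
pipeline corrects within the vmPFC-like mask, matching ROI-restricted
correction for regionally specific claims; whole-volume masks are
supported through the same API. A voxel whose values are identical across
subjects has a degenerate t; it is assigned a large finite statistic
(capped before enhancement) rather than NaN.

The conjunction analysis intersects the voxels significant for
"ambivalent accepts > confident rejects" during the offer phase with
those significant for "confident rejects > ambivalent accepts" during the
commit phase — the two contrasts that share no condition across phases —
each corrected at FWE .05 within the ROI.

## ROI model comparison

Per subject, phase and condition, the mean GLM2 beta over ROI voxels is
paired with the mean signed value of that condition's trials. Two models
compete:

    linear:     y = b0 + b1 v + (1|subject) + e
    quadratic:  y = b0 + b1 v + b2 v^2 + (1|subject) + e

The random-intercept model is fitted by profiling the variance ratio
`lambda = sigma_u^2 / sigma_e^2` on a log scale (coarse grid bracketing,
then bounded scalar minimization to 1e-10), with the `lambda = 0` boundary
compared explicitly and flagged; at the boundary the fixed effects equal
OLS. REML supplies the reported estimates and simulation CIs (5,000 draws
from N(b, Cov(b)), 2.5/97.5 percentiles; "significant" = CI excludes 0);
ML refits feed the likelihood-ratio test and AIC/BIC (k = p + 2 including
both variances; BIC uses the observation count). The quadratic model wins
iff the ML LRT rejects at .05. Satterthwaite p-values are deliberately not
implemented; inference rests on the LRT and simulation CIs.

## Response-time model

RTs are modelled as inverse-quadratic in signed value. Two exclusion
stages: trials beyond 3 SD of the pooled group RT, then trials beyond 3 SD
of the subject's own per-bin mean. Signed value is cut into 5 equal-width
bins on [−1, 1] ("equally spaced"; the equal-count quantile reading is the
noted alternative), and the model's observations are each subject's mean
RT per bin, predicted by the subject's mean signed value in the bin and
its square with a random intercept. A companion fit uses per-subject
z-scored SV as the predictor; signs agree on monotone-linked data
(tested).

## Synthetic data generator

The generator emulates the study conditions: 28 subjects (default), 189
offers in six runs with 10 payout trials, TR 0.91 s. Agent coefficients
are truncated normals centred on the group means (1.057, 0.199, −0.170)
with SDs (2.5, 0.10, 0.10), truncated to the observed per-subject ranges
([−6.42, 9.75], [0.064, 0.547], [−0.547, −0.050]). RTs use
b = (800, −35, −77) ms with 150 ms Gaussian noise, floored at 150 ms (the
floor and noise model are package conventions, configurable).

BOLD volumes (default 20 x 20 x 10 voxels) embed three disjoint regions:
a `vmpfc_like` block carrying an SV-proportional response in the offer
phase and a confidence-proportional response in the commit phase (and
nothing else — the generative claim under test), a `control_like` block
carrying negative-confidence (ambivalence) responses in both phases, and a
`null_like` block with no task signal. A voxel's task signal is the
amplitude-weighted sum of the corresponding GLM1 design columns (identical
HRF and preprocessing conventions as the estimator), so noiseless recovery
is exact by construction and noisy recovery probes estimator efficiency,
not model mismatch. Noise is AR(1) (rho = 0.3, innovation SD 1) plus a
linear ramp and a 120-s sinusoid; runs are padded 20 s past the last
event. **SNR** is defined as the task amplitude in units of the noise
innovation SD; per-subject response gain varies as N(1, 0.3) truncated
at 0.1, adding realistic between-subject heterogeneity.

What the generator does *not* emulate: physiological (cardiac/respiratory)
noise, head motion, spatial autocorrelation of noise, susceptibility
artifacts, nonlinear BOLD saturation, or HRF variability across regions
and subjects. Passing recovery tests therefore demonstrates that the
analysis machinery is correct and well calibrated under its own
assumptions — not that the pipeline is robust to every property of real
data.

## Problem sizes

The test suite and the acceptance script run reduced-scale cohorts chosen
to keep Monte-Carlo error acceptable while staying desk-scale: 12 subjects
x 20 x 20 x 10 voxels x 1000 permutations for the end-to-end
dissociation-recovery replicates (20 cohorts), 200 replicate small-grid
datasets for null calibration of the FWE rate and the LRT, 100 agents for
choice-model recovery, and a 28 x 189 cohort for the RT model. The full
study-scale profile (28 subjects, 5000 permutations) is one configuration
flag away (`n_subjects`, `n_perm`).

## Known limitations

* The logistic MLE carries the classic O(1/n) inflation bias (~+0.02 on
  the slope scale at n = 189 with study-scale effects); recovery is
  assessed by sign and median absolute error, and the bias is documented
  where means are compared.
* With strongly deterministic agents and small sessions (< ~100 trials),
  quasi-separation becomes common; the session size and stratified grid
  of the default design keep it near 1%.
* Group inference in the pipeline is ROI-restricted; whole-volume TFCE is
  available but slower.
* The LMM supports a single random intercept only — no random slopes or
  crossed effects, matching the analyses it serves.
* A signal linear in SV is mildly curved in signed value (SV is the logit
  of `(1+v)/2`), so on very clean synthetic data the offer-phase quadratic
  term occasionally detects that genuine curvature and flips the model
  comparison in a minority of cohorts. The offer-phase "linear" verdict is
  a statement about the dominant shape, not an exact null.
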