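# Methods

## The viscoelastic model

The package treats a peripheral artery as a lumped second-order
mechanical element whose elastic restoring pressure grows exponentially
with wall strain, and takes the photoplethysmogram (PPG) $P_l(t)$ as
proportional to that strain:

$$P_b(t) = \mu \ddot P_l(t) + \eta \dot P_l(t)
  + \exp\{\beta P_l(t) + P_{b\beta_0} + P_{b\beta nl}(P_l(t))\}.$$

Assumptions that matter:

* **Strain–PPG proportionality.** β is expressed *per PPG unit*; a
  constant optical gain change rescales β by the inverse gain, which is
  why downstream analysis uses the dimensionless ratio β_n (invariant
  to gain, asserted exactly in the tests).
* **Constant venous term within the fitted samples.** The two-step
  estimator is exact only when
  $P_{b\beta nl}(P_l(t)) - P_{b\beta nl}(P_l(t_0)) = 0$ on the samples
  used.  The simulator therefore models the venous component as a
  constant exponent offset, making the ground truth exactly
  identifiable.
* **Log-linearity holds above mean pressure.** Below the beat's mean
  pressure the artery is in a markedly stiffer regime; step 2 uses only
  samples with $P_b$ above the per-beat mean.

## Two-step estimation and its fixed-point refinement

Within each R-to-R beat, all signals are differenced against the R-wave
sample $t_0$, removing the unknown constant exponent offset.  Step 1
fits (μ, η, β_A) by OLS after Maclaurin-linearizing the exponential;
step 2 fixes (μ, η), forms the elastic residual
$q = P_b - \mu\ddot P_l - \eta\dot P_l$ and regresses
$\ln\{q(t)/q(t_0)\}$ on $dP_l(t)$ through the origin, restricted to the
above-mean-pressure, $q>0$ mask.

The linearization in step 1 presumes small strain excursion.  At
physiologic excursion (elastic pressure rising 60→99 mmHg over a beat,
i.e. $\beta \cdot \mathrm{amp} \approx 0.5$) the neglected curvature
projects onto the derivative regressors and biases μ by tens of percent
and β by ~3% — measured on noiseless synthetic records.  The estimator
therefore iterates the pair of steps to a fixed point by default: step 1
is refit with the step-2 exponential elastic pressure
$\exp(\hat\beta P_l + \hat c)$ substituted for its linearization (only
μ and η remain in that regression), step 2 is repeated with the updated
(μ, η), and the cycle continues until β changes by less than
`refine_tol` (default 1e-10, at most `max_refine = 30` passes).  On
noiseless model-generated beats this converges to machine precision;
`max_refine = 0` reproduces the plain single-pass procedure, and the
reported β_A is always the single-pass step-1 value.

### Numerical choices

* **Derivatives.** Savitzky–Golay differentiation (window 21 ms, cubic)
  over the whole record; second derivatives of a measured PPG are
  noise-dominated without polynomial-window smoothing.  The filter is a
  linear operator, so the estimator's equivariances are preserved.
* **Signal smoothing.** BP and PPG are smoothed with the zero-order
  Savitzky–Golay filter (same window) before estimation, default on.
  Rationale: every differenced quantity inherits the noise of the
  single reference sample $t_0$; in step 2 that noise enters
  $\ln q(t)/q(t_0)$ as a common offset which the through-origin
  regression maps straight into β.  Measured at 0.5 mmHg BP noise,
  smoothing reduces the median per-beat β error from ~1.9% to ~0.8%.
* **Positivity guard.** The logarithm requires $q>0$; offending samples
  are dropped from the mask, and if $q(t_0) \le 0$ the reference shifts
  to the earliest masked sample with positive residual (logged).
* **Rank handling.** OLS is solved by SVD (`lstsq`); a singular-value
  ratio below 1e-10 (e.g. a flat PPG) is an explicit per-beat error,
  never a silent pseudo-inverse fill-in.  Per-beat errors are isolated:
  the beat is flagged invalid and the record continues.
* **Mask floor.** Step 2 requires at least 30 masked samples (30 ms at
  1000 Hz) — below this the beat is invalid.  Configurable.
* **Exponent cap.** Elastic exponents above 700 raise a simulation
  error (forward direction) or are clipped in reconstruction scoring,
  where a bad fit should yield a bad R², not an overflow.
* **Intercept recovery.** The exponent offset removed by differencing
  is reconstructed as the masked-sample mean of $\ln q - \beta P_l$
  (closed-form LS with β fixed); R² compares the full nonlinear
  reconstruction with measured pressure over the whole beat.  The gate
  default is R² ≥ 0.9.

## Beat segmentation

R peaks are detected Pan–Tompkins-style (5–25 Hz band-pass, squared
derivative, 150 ms integration, peak picking at 25% of the maximum
integrated energy with a 250 ms refractory period, apex refinement on
the band-passed ECG).  Beats are R-to-R windows; $t_0$ is the leading
R sample; the per-beat mean pressure drives the step-2 mask so the mask
adapts to slow drift.  Windows implying heart periods outside
0.3–2.0 s are dropped.

## Normalization and pain mapping

β_n divides β by the *maximum* accepted β inside a no-stimulation
baseline window (default 222–246 s of the standard protocol).  Because
a maximum over noisy estimates is biased upward, β_n carries a small
downward bias that grows with per-beat noise; this is inherent to the
max-based definition.

The pain score eNRS is 0 at or below baseline stiffness and otherwise
$20/(1+\exp(a(\beta_n-1)^{-b}))$, continuous at $\beta_n=1$, strictly
increasing and bounded below 10.  The stimulus-response sigmoid
$10/(1+\exp(aS^{-b}))+1$ is undefined at $S=0$ as printed; the package
defines it by its limit, 1, so zero-level trials are usable.  Both
families are fitted by bounded nonlinear least squares from 8
deterministic log-spaced starts; a start that exhausts its evaluation
budget still contributes its best finite solution (the likelihood is
flat in $a$ when the data saturate).  Aggregation before the stimulus
fit follows mean β_n per stimulation window, then means per level.

Identifiability warning: at the standard levels {0, 0.5, 1, 1.5} with
coupling near (a, b) = (3, 2), the 0-level point carries no information
and the 0.5-level response is saturated at 1, so (a, b) are effectively
identified from two points.  With response noise σ = 0.2 the Fisher
information bounds the median relative error near 10% (a) and 14% (b);
the multi-start NLS operates at that floor, and no estimator can do
materially better under these conditions.

## The synthetic generator

The generator emulates the study conditions end to end: a PPG built
from exactly periodic two-lobe (systolic + dicrotic) von-Mises-style
pulses with *analytic* first and second derivatives, so the simulated
pressure is an exact forward-model evaluation; a triangular-QRS ECG at
each beat onset; i.i.d. Gaussian measurement noise added to the clean
pressure (default σ = 1 mmHg); and the stimulation protocol of seven
64 s trials (20 rest + 24 stimulation + 20 evaluation, levels
1.5/1.0/0.5/0/0.5/1.0/1.5), with per-beat stiffness coupled to the
level through the stimulus sigmoid with (a, b) = (3, 2).  Resting
parameters: μ = 0.02 mmHg·s²/a.u., η = 0.3 mmHg·s/a.u., β = 0.5/a.u.,
exponent offset ln 60 — elastic pressure 60→99 mmHg across unit PPG
amplitude, with viscous and inertial contributions of a few mmHg, at
70 bpm and 1000 Hz.  PPG amplitude attenuation under stimulation is
available but off by default, since a gain change redefines the strain
unit in which β is expressed.

What it does **not** emulate: heart-rate variability, respiratory and
baroreflex modulation, pulse transit delay between ECG and finger PPG,
motion artefacts, colored sensor noise, ectopy, or a strain-dependent
venous term (a constant is used so truth is identifiable; a
non-constant venous term would violate the estimator's core assumption
and carries no recovery guarantee).  Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under the model's own
assumptions — not robustness to everything real recordings contain.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 1000 random draws for
forward-model agreement (to 1e-12 against an independent scalar
transcription); 100 noiseless random-parameter beats for exact recovery
(relative errors ≤ ~1e-8 observed, asserted < 1e-6); ~200 beats at
0.5 mmHg noise for the noisy-recovery median (≈0.7%, asserted < 2%);
~100 beats at 20 mmHg for the gate rejection rate (100%, asserted
> 90%); and one full 448 s protocol block (522 beats) for end-to-end
tracking (≈1.1–1.3% median absolute relative error, asserted < 5%) and
coupling recovery ((3.12–3.18, 1.97–1.98) against (3, 2)).
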