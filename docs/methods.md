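# Methods

`qmrpipe` reproduces, on a fully synthetic digital phantom, a two-arm MR
study design for distinguishing recurrent brain tumor from radiation
necrosis (RN) in mouse models: a multi-contrast quantitative ¹H MRI
pipeline (R1, R2, ADC, MTR, DCE-AUC parametric maps with ROI statistics)
and a ²H MRS arm that follows deuterated-glucose metabolism into lactate
(Lac) and glutamate+glutamine (Glx).  This note records the models, the
defaults and why, what the synthetic data does and does not emulate, and
the numerical choices.

## Signal models and fitting

**R1 — variable flip angle (VFA).**  Spoiled gradient-echo steady state,

    S(θ) = S₀ (1 − E₁) sin θ / (1 − E₁ cos θ),   E₁ = exp(−TR·R1),

fitted per voxel for (S₀, R1) by full nonlinear least squares, initialised
from the DESPOT1 linearisation (S/sin θ regressed on S/tan θ).  Flip
angles are taken as nominal; no B1 correction is applied, so — like the
acquisition protocol it models — VFA R1 inherits any magnetization-transfer
or B1 bias (VFA R1 has been reported up to ~1.8× above inversion-recovery
values in lesions; we note this rather than model it).

**R2 — multi-echo spin echo.**  S(TE) = S(0)·exp(−TE·R2) + C, fitted for
three parameters.  The additive constant absorbs noise-floor and
stimulated-echo offsets; dropping it biases R2 low on offset-contaminated
data (demonstrated in the test suite).  Initialisation is a log-linear fit
of the offset-subtracted echo train.

**ADC — tensor trace.**  ln S = ln S(0) − Σᵢⱼ bᵢⱼ Dᵢⱼ over the six unique
tensor elements, solved by weighted least squares (weights S², the
first-order propagation of the log transform); ADC = trace(D)/3.
b-matrices are inputs (s/mm²), never recomputed from gradient shapes; the
10⁻³ factor that makes D come out in μm²/ms is handled internally and unit
tested.  Rank-deficient encoding schemes are rejected with a diagnostic;
negative-definite fitted tensors are flagged.

**MTR.**  100·(OFF − ON)/OFF in percent.  Voxels with OFF below the
background threshold are masked; values escaping [0, 100] under noise are
flagged out of the mask, not clipped silently.

**Batched nonlinear fitting.**  The VFA and multi-echo fits run as a
vectorised Levenberg–Marquardt over all masked voxels simultaneously
(analytic Jacobians, per-voxel damping, Marquardt diagonal scaling).  This
is numerically the same estimator as per-voxel NLS — verified against
`scipy` on toy problems — but fits a 64×64×21 stack in well under a
minute on one core.  Uncertainties come from the residual variance times
the inverse Gauss–Newton Hessian.

**Preprocessing.**  In-plane Gaussian smoothing with σ = 0.75 voxels,
applied per volume; σ = 0 is the identity.  Whether smoothing precedes
every fit or only display is not fixed by the protocol; here it is
optional per stage, on by default in the study pipeline, and logged.
Conservative ROIs (in-plane Chebyshev erosion of 3 voxels, matching the
truncated kernel support) keep every ROI voxel's smoothing support inside
its own tissue, mirroring ROIs drawn to avoid partial-volume edges.

**Background masking.**  Voxels with mean signal below 5× the estimated
noise floor are never fitted.  The floor is the median of the lowest
intensity decile (Rayleigh background); if that decile is comparable to
the bulk intensity the field of view has no air background and the floor
is zero.  The multiple is config-exposed.

## DCE-AUC

Per-voxel fractional enhancement relative to the mean over baseline frames
1–30 (1-based), normalised by the **maximum of the muscle-ROI-mean**
enhancement curve over early frames 31–120, summed over the 270
post-injection frames and divided by 3 s × 270 = 810 s.  ROI-mean-then-max
is the adopted reading of the muscle normaliser; the alternative
(per-voxel max, then mean) systematically overestimates the factor under
voxel-wise timing jitter and is rejected (a test demonstrates the
difference).  The injection frame is fixed at 30 (config-exposed) so the
printed 810-s divisor holds exactly.  AUC values are per-second of
normalised enhancement, reported as "au".

## ²H MRS quantification

**Spectral model.**  Each 10-minute block's FID is a sum of exponentially
decaying sinusoids (Lorentzian lineshape only).  One frequency and one R2*
per resonance plus a single zero-order phase are shared across the whole
time course; amplitudes are free per block.  The fit is separable
(variable projection): at each step of the nonlinear optimisation over
{fₖ, R2*ₖ, φ} the per-block real amplitudes are solved exactly by linear
least squares.  Parameter SDs — including amplitude SDs — come from the
full-parameter covariance at the optimum (residual variance × pseudo-inverse
of JᵀJ with analytic J), i.e. a Laplace approximation in place of a
Bayesian posterior; on well-conditioned data the point estimates coincide,
which is the rationale for not carrying a sampler.  Fitting starts at the
first acquired complex point; no first-point scaling correction is
applied.  Near-degenerate frequency pairs (closer than half the wider
linewidth) trigger a warning and a flag.

**Amplitude → concentration.**  A_corr = A / [stoich × (1 − e^(−TR/T1)) ×
e^(−TE/T2)], assuming an ideal 90° excitation each TR (adiabatic pulses).
Stoichiometries: HOD 1, Glc 2, Lac 1.7 (two labels, 15% loss), Glx 1.2
(two labels, 40% loss).  T1/T2 defaults (HOD 320/30, Glc 64/32, Lac
297/61, Glx 146/40 ms) are literature-informed assumptions, config-
overridable — the acquisition parameters they correct for are TR 450 ms,
TE 4.27 ms.  Concentrations follow from the natural-abundance HOD internal
reference: the mean corrected HOD amplitude over the two pre-infusion
blocks is assigned 16.35 mM, and uncertainties are propagated to first
order including the reference's own.  Negative point estimates are floored
only in the reported concentration field; the raw signed estimates are
retained and used for ratios.

**Glx:Lac.**  Per-block ratio with propagated SD; blocks where Lac is
within 2 SD of zero are flagged undefined rather than reported.

**Reference calibration.**  Standard addition: OLS of amplitude on added
ΔHOD over {0, 36, 72, 108, 144, 180} mM; the x-intercept magnitude a/b
estimates the endogenous concentration, with a delta-method SE.  The ppm
conversion uses water's 111.1 M of equivalent ¹H sites:
c(mM) = ppm × 10⁻⁶ × 111,100.

## The synthetic phantom

Geometry: 2-D multislice (64×64 over a 16×16 mm² FOV, 21 × 0.5-mm slices
by default), an elliptical brain with a left-hemisphere lesion disk (or
two disjoint disks for the mixed layout), contralateral cortex, and a
ventral temporalis/masseter muscle band.  Through-plane partial volume is
not modelled.

Tissue truths: lesion presets carry the study's group-mean parameter
values (tumor R1 1.08 s⁻¹, R2 14.9 s⁻¹, ADC 0.833 μm²/ms, MTR 24.1%, AUC
0.916 au; RN 1.26 / 17.6 / 0.736 / 30.2% / 0.784; separate admixed-lesion
presets) so noiseless simulate-then-fit round trips are recovery tests
against published-scale numbers.  Cortex and muscle presets are
literature-informed defaults — no normal-tissue values are printed for
this study design.  Across-subject variation draws each subject's
parameters from Gaussians with the tabulated across-subject SDs.

DCE curve family: enhancement is zero through frame 30, then
mono-exponential uptake with slow washout.  No functional form is printed,
so the family is a design choice; the lesion amplitude is calibrated in
closed form so the noiseless pipeline (enhancement → muscle normalisation
→ /810 s) returns exactly the preset AUC target.  The muscle curve (40%
peak within the early window) is the normaliser's ground truth.

Noise: Rician on ¹H magnitude images (complex Gaussian before magnitude),
circular complex Gaussian on raw ²H FIDs — matching how each modality is
recorded.  The default imaging noise is SD = 2% of s0 (SNR 50).

²H kinetics: mono-exponential approach from baseline to plateau after the
infusion onset at 20 min (two 10-min pre-infusion blocks).  Metabolites
start at zero; HOD starts at the 16.35-mM natural abundance and rises
slowly as label exchanges into body water.  Plateaus are design values —
no absolute concentrations are printed — chosen to reproduce the
qualitative cohort ordering: tumor ferments glucose (Lac 6.0 mM ≫ Glx
1.5 mM, terminal Glx:Lac < 1; Warburg effect) while control (Glx 3.5 / Lac
1.0) and RN (3.2 / 1.2) oxidise it (ratio > 1), with ~5× dynamic range in
terminal Lac.  Between-subject plateau jitter is 8% (clipped Gaussian),
consistent with small SEM bars in a controlled preclinical infusion.
Chemical shifts (HOD 4.8, Glc 3.8, Glx 2.4, Lac 1.3 ppm at 76.65 MHz) are
literature conventions.

What passing tests therefore show: that the estimators invert their own
forward models exactly, remain unbiased at realistic SNR, and that the
statistical machinery is calibrated.  What they cannot show: robustness to
B0/B1 inhomogeneity, surface-coil sensitivity profiles, motion, Gibbs
ringing, partial volume, baseline drift, or lineshape departures from
Lorentzian — none of which the generator emulates.

## Statistics

ROI summaries are mean/SD (n−1) over fitted voxels only; excluded voxels
are counted, never imputed.  Cohort tables report the across-subject SD of
per-subject ROI means (not pooled voxel SDs).  Two-sample comparisons use
the Welch t-test by default (the protocol states only "two-tailed
t-tests"; a pooled-variance flag is available), pairs within the mixed
model a paired t-test, and each parameter's family of contrasts is
adjusted by Holm's step-down Bonferroni procedure (the standard reading of
"step-down Bonferroni").  Zero-variance corner cases use explicit
conventions (t = 0, p = 1 for identical data; p = 0 flagged degenerate for
constant nonzero differences).  The terminal-block cohort comparison in
the spectroscopy arm uses the pooled-variance flag: cohorts are small
(n = 4) and balanced, and pooling mirrors the repeated-measures
ANOVA-style analysis this readout stands in for — Welch's df ≈ 3 under
strongly unequal cohort variances makes extreme significance levels
unreachable regardless of effect size.

## Problem sizes and reproducibility

Defaults per run: 64×64×21 imaging stacks; six flip angles; sixteen
echoes; 6+1 diffusion volumes; 300 DCE frames; eleven 10-min ²H blocks of
1,024 complex points at 1,500 Hz.  The cohort-statistics driver uses n = 9
subjects per cohort at 11 slices; the replicate lactate-separation study
runs 100 replicates of n = 4 per cohort.  All randomness flows from
explicit integer seeds through `numpy` SeedSequence spawning; identical
config + seed reproduces byte-identical CSV outputs.

## Known limitations

* No Bloch/pulse-sequence simulation; forward models are the analysis
  equations themselves, so round trips are inverse crimes by construction
  — they validate the estimators, not the acquisition.
* VFA R1 bias (MT/B1) is documented, not corrected.
* T1/T2 correction values for ²H resonances are assumptions, not
  measurements.
* The Gibbs "un-ringing" step of the original processing chain and
  inversion-recovery R1 mapping are out of scope.
* Absolute ²H concentrations depend linearly on the assumed natural
  abundance (16.35 mM); regional water supplies differ.
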