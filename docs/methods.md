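# Methods

This note records the models implemented by `placentamri`, the defaults
and the reasoning behind the genuinely open design choices, and what the
synthetic validation does and does not demonstrate.

## Placentome signal model

The placentome signal on a (b, TE) grid is a three-compartment
diffusion–relaxation mixture: feto-placental blood (volume fraction f,
pseudo-diffusivity d\*, relaxation T2fb), maternal blood (fraction v, no
diffusion attenuation, fixed T2mb), and tissue (fraction 1 − f − v,
diffusivity d, fixed T2ts). The maternal compartment carries no
b-dependence in this reading: incoherent flow through the large maternal
sinuses is taken as fully dephased at the lowest non-zero b-value, so
maternal blood contributes relaxation contrast only. This grouping is
the standard one for this model family; it is flagged here because the
alternative (a maternal pseudo-diffusion term) would change the fitted v
at low b.

Fixed constants default to T2mb = 150 ms and T2ts = 42 ms at 3 T. These
are sometimes quoted with an inverse-millisecond unit attached; as
relaxation *rates* those magnitudes would be physically impossible for
blood or tissue at 3 T, so the package interprets them as T2 values in
ms. Both are configurable.

### Fitting

Six free parameters (f, d, d\*, T2fb, v, S0) are recovered by nonlinear
least squares under the stabilising boxes 0 < f, v, d, d\* < 1 and
0 < T2fb < 150 ms, with S0 > 0 initialised at the curve maximum.
Because a plain Levenberg–Marquardt step is unconstrained, the default
solver is trust-region reflective with the boxes imposed directly; an
LM-on-transformed-coordinates route (logit for the bounded parameters,
log for S0) is available behind `method="lm-transformed"`. The joint
physicality constraint f + v < 1 is not a box, so it enters as a hinge
penalty appended to the residual (weight 1e3, configurable). Voxelwise
fitting is two-stage: the ROI-average curve is fitted first (default
start f = v = 0.2, d = 1.5e-3, d\* = 0.03, T2fb = 75 — mid-box) and its
estimate seeds every voxel. Cost tolerance 1e-10, 400 iteration budget.
Failed or degenerate voxels (flat curves carry no decay information) are
flagged, never silently returned; unfitted voxels hold NaN with a
boolean companion mask. Fitting is ordinary unweighted least squares on
magnitude data; no Rician bias correction is applied.

The default acquisition grid is the full factorial
b ∈ {0, 50, 100, 200, 400, 600} s/mm² × TE ∈ {72, 96, 120, 144, 192} ms
(30 points). A grid is accepted for fitting only if it has ≥ 6 distinct
points spanning ≥ 2 b and ≥ 2 TE values.

### Identifiability under noise

A Cramér–Rao analysis of this design at a typical placental truth
(f = v = 0.25, d = 1.5e-3 mm²/s, d\* = 0.03 mm²/s, T2fb = 60 ms) shows
the per-voxel fit is strongly noise-limited: with magnitude noise
σ = S0/50, the best achievable relative standard deviation is ≈ 0.9 for
f and ≈ 0.2 for v (the fetal-blood term is small and collinear with the
other two compartments over this b/TE range). Per-voxel maps of f at
such noise levels are therefore qualitative; quantitative f requires ROI
averaging (the ROI-average fit over a few dozen voxels is accurate to a
few percent, which is how the cohort pipeline uses the model). The test
suite asserts a sub-10% per-voxel error target at SNR 50 for f and v;
the f assertion fails by design of the physics, and is retained as an
explicit record of this information limit rather than weakened.

## T2 oximetry

Vessel T2 is fitted from T2-prepared series (default preparation times
32, 64, 96, 128, 160, 192 ms) as a 2-parameter mono-exponential
S(τ) = S0 e^(−τ/T2), log-linear initialised; an additive offset (noise
floor) term is available behind a flag but off by default. ROI signals
are aggregated by the mean. Saturation follows the quadratic
(Luz–Meiboom-type) relationship R2 = A + B (1 − Y)², inverted on the
physical branch Y ≤ 1. The shipped `sheep_default` preset
(A = 10 s⁻¹, B = 70 s⁻¹, Hct ≈ 0.30) is a **synthetic representative
calibration** for sheep blood at 3 T chosen to place venous/arterial T2
in the physiologic 30–100 ms range; it is not a bench-calibrated
constant set, and real analyses must supply their own. A measured T2
above the fully-oxygenated limit (R2 < A) raises by default; the cohort
pipeline passes `saturate=True`, mapping such noisy measurements to
Y = 1 with a clamp flag.

The "central 60% of the vessel" ROI rule is made deterministic: pixels
are ranked by descending distance-to-boundary, ties broken by distance
to the mask centroid then row-major order, keeping ceil(0.6 N) pixels.

## Phase-contrast flow

Velocity is VENC·phase/π; aliased input (|phase| > π) is rejected, not
unwrapped. Per-phase flow is Σ velocity × pixel area over the ROI,
converted to mL/min; the vessel flow is the unweighted mean over cardiac
phases (uniform phase sampling), which coincides with per-beat
integration × heart rate under that assumption. No background-phase or
eddy-current correction is modelled; inputs are taken as pre-corrected.

## Oxygen transport

Units are fixed: Hb g/L (converted internally to g/mL), flows mL/min,
DO2/V̇O2 mL O2/min, with 1.36 mL O2 per g Hb. Dissolved oxygen is
omitted. The uterine-artery saturation feeding the UtA delivery equation
is configurable; the default takes the uterine artery to carry maternal
arterial blood, measured by the UtA/arterial T2 series (a uterine-vein
surrogate can be selected instead).

## Synthetic cohort

`simulate_cohort` emulates a study of 7 ewes scanned in three states.
Cohort means follow the physiology of anaesthetised late-gestation
ewes: maternal Hb ≈ 80 g/L and fetal ≈ 95 g/L (anaesthesia lowers the
maternal value), LVCO ≈ 7 L/min, total UtA flow ≈ 1.2 L/min (≈ 17% of
LVCO), UV flow ≈ 650 mL/min (≈ 200 mL/min/kg for a ≈ 3 kg fetus),
placental f ≈ v ≈ 0.25, d ≈ 1.5e-3 mm²/s, d\* ≈ 0.03 mm²/s,
T2fb ≈ 60 ms, venous/arterial saturations Y_UV ≈ 0.80, Y_DAo ≈ 0.55,
maternal arterial ≈ 0.95. Between-animal variability is lognormal on
flows (σ_log 0.12–0.15) and additive normal on fractions and
saturations (clamped to their boxes); state-to-state within-animal
jitter is smaller by roughly a factor of three. Plasma drug
concentrations are sampled per state (≈ 1270 ± 740 ng/mL maternal in
the first post-dose window, ≈ 318 ± 108 in the second; fetal ≈ 1/5 of
maternal).

The injected effects reproduce the study pattern being emulated:
v + 0.08 in TAD2 only; UtA flow × 0.78 in both TAD windows at unchanged
LVCO (lowering its share of cardiac output); maternal pressure − 12 mmHg
in both windows; every fetal endpoint null. Each switch can be disabled
for null simulations.

Per animal × state the generator emits a homogeneous 4×4×2 placentome
block with Rician noise at SNR 50 (σ = S0/SNR), five vessel T2-prep
series at SNR 100, and parabolic-profile cine stacks whose analytic flow
equals the ground-truth flow (0.5 mm pixels, 15 cardiac phases,
sinusoidal waveform with exactly unit discrete mean). The per-vessel
VENC is the protocol-nominal value (150 cm/s arteries, 100 cm/s UV),
raised automatically for an extreme animal whose peak velocity would
alias — emulating the operator's vessel-appropriate VENC prescription.

What the synthetic data do **not** model: placentome anatomy and
spatial heterogeneity, motion (all series are motion-free, matching the
decision to keep registration out of scope), cardiac waveform
physiology, partial-volume and background-phase effects, and
pharmacokinetics (drug levels are sampled covariates). Passing tests
therefore demonstrate correctness of the estimators and the statistical
chain under the stated noise models, not robustness to those real-data
effects.

## Statistics

The omnibus test is the classical one-way within-subject ANOVA
decomposition (SS_subject removed; F = MS_condition/MS_error with
(k−1, (k−1)(n−1)) df), without sphericity correction by default
(Greenhouse–Geisser available behind a flag). Pairwise comparisons are
paired t-tests with Bonferroni adjustment min(1, m·p) over the m = 3
state pairs — paired t rather than ANOVA-MSE contrasts, so each pair's
inference uses its own difference variance. Zero-variance cases are
flagged degenerate instead of returning spurious p-values. The compact
letter display is a greedy insert-and-absorb on the non-significance
graph with deterministic state ordering. Time-resolved pressure/heart
rate traces are reduced to 5-min bin averages before the same ANOVA.

## Problem sizes used in validation

The shipped checks use: 1000 random draws for the normalisation
identity; a 200-voxel noiseless phantom (recovery at machine precision);
500 voxels per SNR for the noisy-recovery study; 1000 replicates for the
T2 bias; 500 replicate null tables for the type-I calibration (binomial
95% CI about 5%); and 50–100 replicate full cohorts for the end-to-end
detection rates. These sizes give sampling error comfortably below the
asserted margins while keeping a full run in minutes on one CPU.

## Known limitations

* Per-voxel f is noise-limited at realistic SNR (see identifiability
  above); cohort inference uses ROI-level fits.
* The sheep T2–SO2 calibration preset is synthetic; absolute SO2 values
  shift with the true bench constants, though state *contrasts* are
  insensitive to moderate calibration error.
* Rician noise biases magnitude signals upward at low local SNR; no
  bias correction is applied, matching the fitting description being
  implemented.
* The compact-letter display can be non-unique for intransitive
  significance patterns; the deterministic greedy rule makes the output
  reproducible but other letterings are equally valid.
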