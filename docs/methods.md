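# Methods

This note records the model the package implements, the choices that were
genuinely open, and what the synthetic validation does and does not show.

## Forward model (the digital subject)

The phantom is an isotropic 3D grid (each dimension ≥ 32 voxels).  An
ellipsoidal brain (semi-axes ≈ 0.30–0.33 of the grid, i.e. ~60 % of the
field of view) contains, from inside out: two ventricle-like CSF
cavities, a white-matter core, a grey-matter shell, and a subarachnoid
CSF layer occupying the outer ~10 % of the brain radius.  A straight
cylinder parallel to B0 runs along the posterior brain surface, *outside*
the brain mask but touching it, standing in for the superior sagittal
sinus; it spans the whole grid in z, so under the periodic FFT
convolution it is exactly an infinite cylinder and the closed-form
interior field χ/3 holds.  Two geometric points are deliberate and
matter:

* **The cortex does not touch the mask boundary.**  Background-field
  removal treats any field explainable by sources at or beyond the mask
  boundary as background; a cortical shell hugging the boundary would be
  removed with it.  The subarachnoid layer plays the role of the margin a
  generously drawn processing mask has in vivo.
* **The vein is outside the inversion domain.**  A thin, strongly
  paramagnetic cylinder inside the domain leaves cone-shaped inversion
  artifacts that bias tissue region means; outside, its field is removed
  as background, and blood is measured from unfiltered phase anyway
  (filtered maps are unreliable at the mask edge).

Compartment constants: χ (ppm, relative to CSF): WM −0.03, GM +0.02,
venous blood +0.27; R2\*0 (s⁻¹): CSF 1, GM 16, WM 19, blood 30; baseline
magnitudes 1.0 / 0.85 / 0.70 / 0.90.  True blood volume: WM
1.91 mL/100 g, GM 3.85 mL/100 g (literature values), scaled per subject
by a lognormal factor (σ = 0.35) matching the ~40 % between-subject
coefficient of variation of healthy cohorts; the vessel is 100 % blood.
Relaxivities: tissue r2\* = 85, blood 30 (mM⁻¹s⁻¹) — the tissue value is
the in-vivo scale estimate the recovery tests target, and the 2.8×
tissue/blood ratio reproduces the known overestimation of
relaxation-based CBV.

The bolus is a gamma-variate first pass (shape 3, scale 1.5 s, ±5 %
per-subject jitter) plus one damped, dispersed recirculation echo (delay
10 s) plus a saturating plateau with time constant 6 s.  The first 14
frames are exactly zero; the maximum equals the configured peak (default
5 mM, range of interest 5–10 mM) and the late tail converges to
peak/ratio with ratio 9.  Tissue concentration is
(CBV/100)·ρ·(1−Hct_SV)/(1−Hct_LV) times the blood curve; the vein carries
the blood curve itself.

Per frame, susceptibility = χ0 + 0.308 ppm/mM · [CA]; the field is the
FFT dipole convolution D(k) = 1/3 − kz²/|k|², D(0) := 0 (z = B0;
demodulated-field convention; the identical kernel object serves
simulation, background removal and inversion), plus a global drift
(default 0.3 ppb per 1.24 s frame — the drift magnitude is not a
measured quantity and is a configurable free parameter).  Phase is
γ·B0·TE·10⁻⁶·field wrapped to (−π, π]; magnitude decays with
compartment-specific relaxivity; complex Gaussian noise of SD
noise_sd·s0 per voxel makes magnitude Rician and phase noise scale with
1/SNR.  Not modelled: EPI distortion and pixel shift, slice gap
(the grid is 3D isotropic), T1 enhancement, partial-volume mixing,
bolus delay/dispersion heterogeneity.

## Reconstruction

**Unwrapping** is quality-guided region growing: voxels enter in order of
local wrapped-gradient coherence weighted by magnitude, so low-noise
regions resolve first; disconnected mask components keep independent
2π·k offsets; voxels whose neighbourhood stays inconsistent are counted
as residues, never silently fixed.  A subsequent **temporal alignment**
re-wraps each voxel's curve around its own baseline mean (frames 5–14):
this removes per-frame global offsets and the vein's spatially
unresolvable 2π ambiguities, replacing the manual ±2π corrections an
operator would apply.  It assumes the true per-voxel excursion within the
baseline and steady-state windows stays below π — true at these field
strengths/TE for blood concentrations up to ~10 mM peak, *provided the
post window lies past the first pass*; scaled-down runs therefore use at
least 50 frames.  Frames at the bolus peak remain wrong near the vein
(the truth itself exceeds π per voxel step); the measurement windows
avoid them.

**Background removal (PDF)** fits susceptibility sources supported
outside the mask to the interior field by least squares (CG on the
normal equations) and subtracts their field.  Three implementation
points:

* *Early stopping is the regulariser.*  Run to convergence, the
  unconstrained exterior basis can reproduce — and therefore remove —
  most of the interior-source field as well (measured ~40 % of the field
  RMS of even a compact, central source).  The default (60 iterations,
  tolerance 5·10⁻³) removes an exterior point source's interior field to
  ~2 % while preserving interior region-mean differences to a few
  percent.
* *The removal must act as one linear projection across time.*
  Early-stopped CG is nonlinear in its input, and per-frame fits corrupt
  post-minus-pre differences.  The series is therefore split into the
  baseline-window mean plus a baseline-subtracted dynamic remainder, and
  the remainder — low-rank in time (bolus mode + noise) — is factorised
  by a temporal SVD with the fit run once per retained mode (≤ 8).  This
  is also ~an order of magnitude cheaper than per-frame fitting.
* *Fidelity weights are uniform inside the mask.*  Magnitude weighting
  (supported by the API, appropriate when noise dominates) up-weights the
  bright CSF ring just inside the boundary, which is exactly where
  exterior mimicry of cortical field changes is decided; with smooth
  synthetic magnitudes it biased cortical Δχ by ~+30 %.
* The mask-mean of every frame is removed explicitly: a uniform offset
  carries no source information and the CSF shift re-references each
  frame downstream anyway.

**Inversion** offers thresholded k-space division (TKD; kernel values
|D| < t replaced by sign(D)·t, default t = 0.10 — at 0.15 region means
came out 10–15 % low on this geometry; an optional point-spread
rescaling by the mean kernel attenuation is available but off by
default, because after PDF it overcorrects) and a morphology-enabled
variant minimising λ‖W(Dχ−f)‖² + ‖M∇χ‖₁ (λ on the data term, so larger λ
→ higher contrast; IRLS with CG inner solves; W = normalised magnitude;
M = voxels below the 70th percentile of magnitude gradient).  The λ
grid {100 … 5000} reproduces the direction of the contrast trend; the
absolute λ scale depends on the normalisation conventions and is not
comparable across implementations.  The GM−WM difference saturates at
the top of the grid, so the monotonicity check allows wiggle of 1 % of
the swept range there.

**Known bias:** the *absolute* (baseline) cortical susceptibility level
through background removal is substantially underestimated — the shell's
harmonic field component is genuinely indistinguishable from background.
This affects static maps, not the CA-induced differences the perfusion
quantities use (the baseline/dynamic split above isolates them), and is
a recognised limitation of background-removed QSM near the cortex in
vivo as well.

## Reference selection and quantification

Candidates are the ventricular CSF voxels; the magnitude signal-range
criterion keeps the `thresh_range` % with the smallest max−min (rank
order, ties by voxel index, at least one pixel); the tail-to-peak
criterion drops the `thresh_tailpeak` % most extreme ratios — half from
each side, counts rounded half-up (the split is not prescribed; symmetric
trimming is this package's choice).  Ratios are baseline-referenced
((tail−baseline)/(peak−baseline)): raw susceptibility values carry an
arbitrary offset, so an un-referenced ratio would be offset-dependent.
The peak window is the five frames centred on the whole-brain magnitude
minimum (clipped at the series ends); the tail is the last five frames;
the baseline window is frames 5–14 (1-based) throughout; the post-CA
steady-state window is the last 7 frames (the midpoint of the 4–10 range
a per-subject visual inspection would choose).

Shifting subtracts the selection-mean curve per frame and adds back its
baseline level, so the reference is flat at baseline and all spatial
differences are preserved; the same scalar series corrects the
unfiltered phase for drift before the vein measurement.  Vein
susceptibility uses the infinite-cylinder relation per window (guarded
against the magic angle |3cos²θ−1| ≤ 0.05).  Regional Δχ uses WM/GM
masks eroded by 1 voxel and the relaxivity fit uses the brain mask
eroded by 2 voxels (mask-edge susceptibility values are unreliable);
regional CBV is computed from regional-mean Δχ (the voxelwise map is
also provided — with a common blood denominator the regional mean of the
map equals the regional-mean route).  The relaxivity regression pools
whole-ROI means of ΔR2\* against [CA] from frame 15 to the end
(frames 1–4 excluded as not in steady acquisition, 5–14 because they
define zero), unweighted OLS.

## Validation design and problem sizes

* Worked-example arithmetic (expected concentration/Δχ table): closed
  form, exact at the printed rounding.
* Forward–inverse consistency and noiseless CBV recovery: 64³ grid, 70
  frames, one subject (≈ 20 s).  CA-induced regional Δχ recovers within
  10 %, CBV within 15 %.
* Stochastic recoveries: 40³ grid, 50 frames, 10 seeds each; the mean
  over seeds is asserted (individual seeds scatter by up to tens of
  percent in WM at this size).  CBV at SNR 50 within 25 %; relaxivity at
  SNR 100 within 5 %.
* Repeatability: 6 subjects × 2 visits at 40³/50, subject-specific CBV
  scale, per-visit drift and noise; ventricular artifacts are injected
  into 10 % of CSF voxel curves as constant offsets ~N(0, 0.15 ppm) over
  the last 7 frames — large against tissue Δχ (~0.01 ppm) and within the
  trim capacity of the 30 % tail-to-peak threshold.  The ICC (two-way
  random effects, single measure, absolute agreement, from the ANOVA
  mean squares) at 30 % beats 0 %, and the sweep's ICC optimum falls at
  the same threshold on this dataset.

What passing these tests does *not* show: performance under EPI
distortion, slice gaps, motion, real pulsation artifacts (the injected
spikes are an idealisation), partial volume, vessel curvature, or
deviations of χ_mol and hematocrit from their assumed values.  One
behaviour differs from real data by construction: the signal-range
criterion's benefit saturates here (more pixels only average noise), so
the sweep over `thresh_range` rises with pixel count instead of
preferring small fractions — the phantom's CSF pixels are homogeneous in
a way real ventricles are not.

## Numerical conventions

All susceptibilities are ppm; phase↔field conversion is the single
factor γ·B0·TE·10⁻⁶ (`AcquisitionParams.phase_per_ppm`); ppm↔mM goes
through χ_mol with the 10³ factor in one routine.  Voxel indices are
0-based internally; time points are quoted 1-based in configuration to
match protocol language.  Every run is deterministic given its config
(seeds included), which round-trips losslessly through JSON and is
persisted with a hash next to the outputs.
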