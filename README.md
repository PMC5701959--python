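# dynqsm

Estimating MRI contrast-agent concentration from dynamic quantitative
susceptibility mapping (QSM), and deriving steady-state cerebral blood
volume (CBV) from it — implemented and validated end to end on a digital
brain phantom with a dipole-convolution forward model.

## The problem

In dynamic susceptibility contrast MRI (DSC-MRI), the concentration of a
gadolinium contrast agent (CA) is usually inferred from the magnitude
signal via the change in transverse relaxation rate, ΔR2\* = −(1/TE)·ln(S/S0).
That requires the relaxivity r2\* — which is unknown in vivo and differs
between blood and tissue, biasing absolute perfusion values.  The phase of
the same acquisition carries an alternative, relaxivity-free route: a
paramagnetic CA raises tissue magnetic susceptibility χ in direct
proportion to its concentration,

    [CA] = (χ_Gd − χ_0) / χ_mol ,          χ_mol = 308 ppm/M for Gd

and χ can be reconstructed from the measured field (phase) by dipole
deconvolution (QSM).  For a long vessel at angle θ to B0 the closed form

    χ_cyl = 6 φ / (γ · TE · (3 cos²θ − 1) · B0)

applies directly to the (unfiltered) phase.  With the susceptibility
change of tissue and of pure blood between baseline and the post-bolus
steady state, blood volume follows from

    CBV = 100 · (1/ρ) · (1 − Hct_LV)/(1 − Hct_SV) · Δχ_tissue / Δχ_blood

(ρ = 1.04 g/mL, Hct_LV = 0.45, Hct_SV = 0.25), in mL/100 g.  The catch:
QSM maps have an arbitrary, time-varying offset (inversion null space plus
scanner B0 drift), so every time point must be re-anchored to a reference
the CA never reaches — ventricular CSF.  Selecting *reliable* CSF
reference pixels is the crux, and this package implements the three-step
selection (ventricular ROI → smallest magnitude signal range → trimming of
extreme tail-to-peak ratios of the re-anchored whole-brain curve) and
quantifies how much the last criterion buys in test–retest repeatability.

Because no real acquisition ships with ground truth, everything is
exercised on a synthetic subject: an ellipsoidal brain with ventricles, a
grey-matter shell, a white-matter core, subarachnoid CSF and a draining
vein parallel to B0, driven by a gamma-variate bolus with recirculation
and a steady-state tail, imaged through the same dipole forward model the
reconstruction inverts, with T2\* decay, B0 drift, phase wrapping and
complex noise.

## Worked example

```python
from dynqsm.config import AcquisitionParams, InversionConfig, RunConfig
import dynqsm

cfg = RunConfig(grid_shape=(48, 48, 48), phantom_seed=1, noise_seed=2,
                noise_sd=0.02,           # SNR 50
                acquisition=AcquisitionParams(n_timepoints=70,
                                              b0_drift_rate=0.3),
                inversion=InversionConfig(method="tkd"))
res = dynqsm.run_pipeline(cfg, outdir="results/run_default")
```

or `python analysis/01_simulate_phantom.py` followed by
`python analysis/03_quantify_cbv.py`, which prints:

```
CSF reference: 20 pixels (thresh_range 10%, thresh_tailpeak 30%)
blood delta-chi: 0.171 ppm
 region  CBV qsm  CBV dR2*   true
     wm     2.34      6.16   2.16
     gm     4.78     12.51   4.35
  brain     3.44      7.82    nan
tissue relaxivity r2* = 81.9 /mM/s (r = 0.995, n = 56; simulated with 85)
```

Reading this: the vein's susceptibility change (0.171 ppm) matches the
0.556 mM steady-state blood concentration × 0.308 ppm/mM.  The
susceptibility-based CBV lands near the phantom truth in both tissues,
while the ΔR2\*-based variant overestimates by roughly the tissue-to-blood
relaxivity ratio (85/30 ≈ 2.8×) — the bias the phase-based method exists
to avoid.  The relaxivity fit recovers the simulated tissue r2\* from the
pooled post-bolus frames.

The numbered scripts under `analysis/` run the full study: simulation
(01), reconstruction with diagnostics (02), quantification (03),
test–retest repeatability and CSF-threshold sweeps with injected CSF
artifacts (04), the regularisation sweep of the GM−WM CBV difference
(05), and the synthetic-cohort age regression (06).  Tables land in
`results/`.

## Layout

```
src/dynqsm/        phantom, kernels, unwrap, qsm, csf_reference,
                   perfusion, evaluation, pipeline, io, config
analysis/          numbered study drivers (simulate → ... → cohort)
tests/             unit, property and end-to-end acceptance tests
docs/methods.md    model assumptions, numerical choices, limitations
```
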