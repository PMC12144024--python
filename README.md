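# waterpet

Quantitative cerebral blood flow (CBF) analysis for dynamic ¹⁵O-water PET,
built to study how the choice of image reconstruction — and the effective
spatial resolution it leaves in the image — changes the CBF values a kinetic
analysis reports.

It is aimed at PET physicists and kinetic-modelling researchers who want a
reproducible, fully synthetic testbed for the whole chain: arterial input
handling, one-tissue-compartment quantification (regional and voxel-wise),
volume-of-interest construction, effective-resolution estimation from
image-quality-phantom recovery curves, and the comparison statistics.

## The model

The PET time–activity curve in a region or voxel is modelled with the
single-tissue compartment model with fitted arterial blood volume:

    C_PET(t) = (1 − V_A) · K₁ · [C_A ⊗ e^(−k₂ t)](t) + V_A · C_A(t)

with uptake rate **K₁** (mL/cm³/min; for ¹⁵O-water, read as CBF), clearance
rate **k₂** (1/min), fractional arterial blood volume **V_A**, and arterial
input function **C_A**. K₁/k₂ is the distribution volume of water, V_T.

Two quantification routes are provided:

* **regional** — weighted non-linear least squares on a VOI mean TAC
  (`fit_regional`), optionally with the input delay as a free parameter;
* **voxel-wise** — a basis-function implementation (`fit_voxelwise_basis`):
  the convolution is precomputed on a grid of k₂ values, reducing each voxel
  to a tiny constrained linear problem.

The measured input function can be calibrated to discrete blood samples, and
subject-specific delay and dispersion (monoexponential kernel, time constant
τ) are estimated by fitting the model to the whole-brain TAC over a grid of
τ values, selecting the τ with the lowest residual sum of squares.

Effective spatial resolution of a reconstruction is estimated by matching
measured sphere recovery coefficients of a NEMA image-quality phantom
(six spheres, 10–37 mm, 22.3 kBq/mL over a 2.2 kBq/mL background) against a
simulated library of recovery curves for Gaussian blurs of 1.0–14.0 mm FWHM
in 0.1 mm steps; post-filters add in quadrature,
`effective = sqrt(unfiltered² + filter²)`.

Everything runs on synthetic data: a concentric-shell digital head phantom
(deep grey core, white-matter shell, cortical shell, extracerebral layer)
with known K₁/k₂/V_A maps, a gamma-variate arterial input with delay and
dispersion, frame-integrated acquisition on the default 22-frame / 6-minute
schedule, reconstruction emulated as a 3D Gaussian point-spread function,
and duration-scaled noise.

## Worked example

```python
import waterpet as wp

# a synthetic subject at 6.5 mm effective resolution
phantom = wp.make_brain_phantom()
aif = wp.make_aif()
dyn = wp.simulate_dynamic_pet(phantom, aif, effective_fwhm=6.5, seed=0)

# VOIs and the regional fit
gm = wp.VoiMask(phantom.gm_mask, phantom.voxel_size, "GM")
tac = wp.extract_tac(dyn, gm)
fit = wp.fit_regional(tac, aif)
print(f"GM: K1 = {fit.K1:.3f} mL/cm3/min, k2 = {fit.k2:.3f} 1/min, "
      f"VA = {fit.VA:.3f}, VT = {fit.VT:.3f}")
```

```
GM: K1 = 0.464 mL/cm3/min, k2 = 0.550 1/min, VA = 0.032, VT = 0.845
```

The fitted grey-matter K₁ (0.464) sits below the phantom's true grey value
(0.55): at 6.5 mm resolution the grey-matter signal is partly smeared into
neighbouring tissue — exactly the partial-volume effect the package is built
to quantify.  The distribution volume (0.845) stays near the tissue value of
0.90 because spill-over dilutes K₁ and k₂ largely together.

The same pipeline is scriptable from the shell:

```bash
waterpet simulate --out-dir subj0 --fwhm 6.5
waterpet voi --gm subj0/gm.nii --wm subj0/wm.nii --out-dir subj0
waterpet run-experiment --out-dir results/experiment --seed 1
```

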