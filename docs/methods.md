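# Methods

This note records the models, numerical choices, and design decisions behind
`waterpet`, and what its synthetic tests do and do not establish about real
data.

## Kinetic model and quantification

The tracer model is the single-tissue compartment model with fitted arterial
blood volume,

    C_PET(t) = (1 − V_A) K₁ [C_A ⊗ e^(−k₂ t)](t) + V_A C_A(t).

For ¹⁵O-water the first-pass extraction is near-complete, so K₁ is reported
as CBF (mL/cm³/min).  Time is handled in seconds internally; K₁ and k₂ are
per-minute at every API surface.  The convolution treats the sampled input
as piecewise linear and integrates each segment against the exponential
kernel exactly (an exponential-integrator form of trapezoidal quadrature);
on the default 0.5 s grid the constant-input closed form is reproduced to
machine precision, and halving the grid step changes the model curve by
well under 0.1%.

Acquisition is frame-integrated: model values are averaged over each frame
of the schedule by trapezoidal integration of the fine-grid curve (exact for
piecewise-linear curves when frame edges lie on grid points, which the
default 0.5 s grid guarantees).  The default schedule is 22 frames over
6 minutes (1×10, 8×5, 4×10, 2×15, 3×20, 2×30, 2×60 s).

**Regional fits** minimize duration-weighted least squares (w ∝ frame
duration — longer frames have lower variance under count statistics;
uniform weighting is available) with bounds K₁ ∈ [0, 3] mL/cm³/min,
k₂ ∈ [0.01, 5] 1/min, V_A ∈ [0, 0.3], and, when requested, input delay
∈ [−15, 15] s.  Three fixed multistart initializations (low/mid/high flow)
are tried; the best converged fit by residual sum of squares wins, so the
fit is deterministic.

**Voxel-wise fits** use the basis-function method: for each k₂ⱼ on a grid
the frame-averaged basis Bⱼ = C_A ⊗ e^(−k₂ⱼt) is precomputed; each voxel
then solves the 2-parameter linear problem y ≈ θ₁Bⱼ + θ₂A (A the
frame-averaged input) under θ₁ ≥ 0, 0 ≤ θ₂ ≤ 1, evaluated candidate-wise
(interior solution plus the constraint edges), and the j with minimal RSS
is kept; V_A = θ₂, K₁ = θ₁/(1 − θ₂), k₂ = k₂ⱼ.  The default grid is 200
log-spaced values in [0.05, 3] 1/min: the ~2% spacing keeps the K₁
discretization error for off-grid clearance values below ~0.5%, which is
what lets voxel-wise and regional estimates agree within 1% on noise-free
data.  (A 100-point grid leaves ~1.4% error — too coarse for that
agreement.)  Voxel-wise V_A is bounded by 1 rather than 0.3; the regional
bound reflects physiology, while the voxel bound only has to keep the
linear subproblem well-posed (a configurable choice).

## Arterial input function

The synthetic input is a gamma-variate bolus (onset 15 s, shape α = 3,
scale β = 5 s, so the peak sits at 30 s) plus a low recirculation plateau
(12% of peak, 25 s rise, 600 s decay), peak-normalized to `dose_scale`
(default 50 kBq/mL).  Dispersion is modelled as convolution with
(1/τ)e^(−t/τ); the explicit inverse uses C_true = C_meas + τ·dC_meas/dt
after an optional 3-point moving-average smoothing (edge-padded).  Delay is
linear-interpolation shifting with zero fill outside the support.

Delay/dispersion estimation follows the forward-modelling route: for each τ
on a grid (default 0–20 s, 1 s steps) the supplied curve is dispersed and
the kinetic model fitted to the whole-brain TAC with delay free; the τ with
minimal RSS wins.  No deconvolution of measured data is performed during
estimation, which avoids noise amplification.  Consistently, the synthetic
cohort defines the brain input as the delay-shifted, dispersed transform of
the "sampled" curve, so the estimator's recovered (τ, Δt) are directly the
generator's — on noise-free data they are recovered to within one grid step
and 0.5 s.  With realistic noise the τ estimate can drift along the known
delay–dispersion trade-off (the RSS surface is shallow in that direction);
this mirrors practice and feeds through as between-subject variability, not
between-method bias, because one estimate per subject is reused for every
reconstruction.

Calibration to discrete blood samples multiplies the curve by the mean of
per-sample ratios (sample / interpolated curve value) — with two samples the
natural estimator, and exactly scale-equivariant.

## Volumes of interest

WB is the union of the GM and WM masks.  CWM emulates a centrum semiovale
VOI: the WM mask is smoothed with a 7 mm-FWHM Gaussian (per-axis σ in voxel
units, so anisotropic voxels are handled) and the 20 cm³ of WM voxels with
the highest smoothed value are selected.  Selection is exact top-N, so the
realized volume is within one voxel of the target.  Deep inside a large WM
mask the smoothed field plateaus at exactly 1.0, making ties common; they
are broken toward the WM centroid (then by flat index), which keeps the
construction deterministic and selects the deepest white matter.  CWM is
restricted to original WM voxels so smoothing cannot recruit other tissue.

## Synthetic head phantom

The phantom is four concentric structures (inside out): a deep grey-matter
core (80 cm³; thalamus/basal-ganglia analogue), a white-matter shell
(220 cm³, ≈15 mm thick), a cortical grey-matter shell (250 cm³), and an
8 mm extracerebral layer with low perfusion (K₁ = 0.13) that is not part of
any brain mask.  Defaults: GM K₁ = 0.55 and WM K₁ = 0.25 mL/cm³/min,
V_T = 0.90 / 0.85, V_A = 3.5% / 1.5%, voxel size 1.97 × 1.97 × 2.79 mm,
64 × 64 × 40 grid.

The shell arrangement is deliberate: the CWM VOI selects the deepest white
matter, and in a real head that tissue lies within roughly a centimetre of
grey matter (cortex above, deep nuclei below).  With the WM shell, the
selected CWM sits ~7 mm from grey matter on both sides and reconstruction
blur produces the expected spill-in; with a solid WM core it would sit
~40 mm from any grey matter and no realistic point-spread function would
reach it, suppressing the very mechanism under study.  The scalp layer
likewise prevents the brain boundary from being an artificial tissue/air
cliff, which would exaggerate whole-brain signal loss under blur.

Simulation: each voxel's noise-free TAC is the frame-averaged model
prediction from its true parameters (the model is linear in K₁ and V_A
given k₂, so only distinct k₂ values need a convolution; if within-tissue
variation creates many, they are quantized to 64 levels); each frame is
blurred with an isotropic 3D Gaussian at the reconstruction's effective
FWHM; zero-mean Gaussian noise with σ = noise_scale·√(activity/duration)
is added (default noise_scale = 2 kBq/mL·√s, giving ~10–20% noise at the
voxel level in peak frames).  Gaussian duration-scaled noise is a standard
surrogate for reconstructed-PET noise; sinogram-level Poisson noise is out
of scope because no tomographic operator exists here.  Because σ ∝
√activity, voxels whose blurred activity is tiny go negative with
probability approaching one half; the "small negative fraction" guarantee
(<5%) therefore applies over the brain support, where it is ~2% at
defaults, not over the surrounding air.

## NEMA phantom and effective resolution

The digital image-quality phantom is a 9.7 L elliptical-cylinder body
(semi-axes 150 × 115 mm, length 180 mm) at 2.2 kBq/mL with six spheres
(10, 13, 17, 22, 28, 37 mm internal diameter) at 22.3 kBq/mL on a 57.2 mm
ring in the central slice; the lung insert is omitted since recovery
analysis uses only sphere interiors and nearby background.  A voxel belongs
to a sphere if its centre is inside the radius; recovery coefficients are
the mean image value in the true sphere interior divided by the true sphere
activity.  On the default 1 mm grid this discretization makes the unblurred
phantom's recovery exactly 1 and leaves the 37 mm sphere at ~0.99 under a
1 mm blur.

The library blurs the phantom at 1.0–14.0 mm FWHM in 0.1 mm steps.  The
blur is evaluated on a crop around the spheres (margin 4σ of the widest
kernel, edge-extended into the uniform background) — exact for the sphere
interiors and ~20× cheaper than full-volume filtering; results are cached
per (phantom, FWHM).  Matching minimizes the RSS over the six spheres, ties
going to the smaller FWHM; post-filters combine in quadrature (the
Gaussian-semigroup identity, verified in recovery space to 0.005).  The
axial [1 4 1] z-filter of the emulated scanner is excluded from the
quadrature, mirroring transaxial-only resolution accounting.  Noise-free
round trips recover the generating FWHM exactly on-grid and to the nearest
grid point off-grid.

## Reconstruction catalog

The catalog ships 14 OSEM-family entries (4 plain OSEM with 3/5/7/10 mm
filters, TOF-OSEM, 6 TOF-PSF iteration variants, and 3 TOF-PSF
subset/filter variants) and 6 BSREM entries (β = 100…600), with
TOF-PSF-3i16s-5mm as the clinical reference.  Each entry carries an
emulated unfiltered effective resolution; filtered resolutions follow by
quadrature and span 5.5–12.6 mm.  Where only a range is published for a
family, per-method values are interpolated monotonically within it (BSREM
resolution increasing with β, TOF-PSF resolution decreasing with
iterations); these are the package's emulation constants, not measurements.

## The synthetic experiment

`run_experiment` simulates a cohort (default 8 subjects) with ~25%
between-subject lognormal variation of K₁, per-subject delay (2–8 s) and
dispersion (3–10 s), one simulated scan per reconstruction method, input
timing estimated once per subject on the reference method's whole-brain
TAC, both quantification routes in WB/GM/CWM, and then the comparison
statistics: per-method mean ± SD and GM/CWM ratio (one decimal, half away
from zero, computed in decimal so printed-precision arithmetic behaves like
hand arithmetic), median relative percentage-difference matrices (entry
(A,B) normalizes by the column method B; the matrix is intentionally not
antisymmetric, and the convention is recorded here and in the output
metadata), exact two-sided Wilcoxon signed-rank tests against the reference
(zeros dropped; exact null distribution at cohort scale), Shapiro–Wilk
normality checks, and OLS regressions of per-method mean CBF on effective
FWHM with t-based slope intervals and Fisher-z intervals for Pearson r.  No
multiple-testing correction is applied; p-values are reported raw.

Statistical routines are scipy/pandas-backed (`scipy.stats.wilcoxon`,
`shapiro`, `linregress`); tests cross-check them against brute-force
enumeration (all 2⁸ sign patterns), an independent reference implementation
value, and hand-computed OLS fixtures.

Problem sizes are chosen so the full experiment (8 subjects × 20 methods,
64 × 64 × 40 grid, 22 frames, 200-basis voxel fits over ~50 k voxels)
completes in a few minutes on one CPU.

## What the synthetic tests do and do not show

They establish correctness of the numerics (convolution, integration,
fitting, recovery computation, statistics) against independent oracles, and
they reproduce the *mechanism* linking effective resolution to regional
CBF: grey-matter CBF decreases and central-white-matter CBF increases with
FWHM, with |r| well above 0.8 in both quantification routes, and whole-brain
CBF is the most stable region between methods.  They do not reproduce
subject-level physiology: the phantom has smooth convex interfaces rather
than folded cortex (so absolute spill-over magnitudes and GM/CWM ratios
differ from real heads), no motion, no attenuation/scatter physics, and
reconstruction is an isotropic Gaussian rather than an iterative algorithm
with spatially varying, count-dependent resolution and noise correlation.
Passing here means the pipeline is sound, not that a particular scanner
will show these exact numbers.

## Known limitations

* One-tissue model only; no PS-limited flow correction, no two-tissue
  variants.
* The basis-function θ₁ ≥ 0 constraint is enforced by candidate evaluation
  (interior + edges), which is exact for this 2-parameter problem but does
  not generalize to more parameters.
* Dispersion correction by differentiation amplifies noise on measured
  curves; the forward-modelling estimator is preferred and the explicit
  correction is provided for completeness.
* The experiment regresses CBF on the catalog's nominal effective
  resolutions; estimating each method's resolution from simulated phantom
  scans first is possible with the same modules but is not wired into the
  default experiment loop.
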