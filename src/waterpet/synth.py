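"""Synthetic data generation: brain phantoms, dynamic PET, NEMA IQ phantom.

Every input the pipeline needs can be generated here, so the full analysis
is testable end-to-end without any acquired data:

* :func:`make_brain_phantom` — a concentric-ellipsoid two-tissue head
  (white-matter core, grey-matter shell) with ground-truth K1/k2/VA maps;
* :func:`simulate_dynamic_pet` — frame-integrated dynamic PET from the
  one-tissue model, with reconstruction emulated as a 3D Gaussian blur at a
  stated effective FWHM plus duration-scaled Gaussian noise;
* :func:`make_nema_phantom` — a digital NEMA image-quality phantom (six
  spheres, 10–37 mm, in a 9.7 L background tank) for recovery-coefficient
  analysis.

Reconstruction itself (OSEM/BSREM) is out of scope; its resolution effect is
what the Gaussian point-spread function emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._conv import expconv
from .frames import FrameSchedule
from .kinetics import SEC_PER_MIN, frame_average

__all__ = [
    "BrainPhantom",
    "DynamicImage",
    "NemaPhantom",
    "TissueParams",
    "make_brain_phantom",
    "simulate_dynamic_pet",
    "make_nema_phantom",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_VOXEL_SIZE = (1.97, 1.97, 2.79)  # mm

NEMA_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)  # mm, internal
NEMA_SPHERE_ACTIVITY = 22.3  # kBq/mL
NEMA_BACKGROUND_ACTIVITY = 2.2  # kBq/mL
NEMA_RING_RADIUS = 57.2  # mm, sphere-center ring in the central slice
NEMA_BODY_VOLUME_L = 9.7


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth kinetic parameters for one tissue class."""

    K1: float  # mL/cm3/min
    VT: float  # mL/cm3 (k2 = K1 / VT)
    VA: float  # unitless fraction

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.VT <= 0:
            raise ValueError("K1 >= 0 and VT > 0 required")
        if not 0.0 <= self.VA < 1.0:
            raise ValueError("VA must be in [0, 1)")

    @property
    def k2(self) -> float:
        return self.K1 / self.VT


#: Default tissue parameters: grey matter K1 ~0.55, white matter ~0.25
#: mL/cm3/min, distribution volumes near 0.9, small arterial blood volumes.
DEFAULT_GM = TissueParams(K1=0.55, VT=0.90, VA=0.035)
DEFAULT_WM = TissueParams(K1=0.25, VT=0.85, VA=0.015)
#: Extracerebral (scalp/soft-tissue) perfusion is low but not zero; the
#: layer keeps the brain boundary from being a tissue/air cliff.
DEFAULT_SCALP = TissueParams(K1=0.13, VT=0.80, VA=0.01)


@dataclass
class BrainPhantom:
    """Two-tissue digital head with ground-truth parameter maps."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    K1_map: np.ndarray
    k2_map: np.ndarray
    VA_map: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        if (self.gm_mask & self.wm_mask).any():
            raise ValueError("GM and WM masks must be disjoint")
        if np.any(self.K1_map < 0) or np.any(self.k2_map < 0):
            raise ValueError("true K1 and k2 must be >= 0")
        if np.any(self.VA_map < 0) or np.any(self.VA_map >= 1):
            raise ValueError("VA must be in [0, 1)")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.gm_mask | self.wm_mask

    @property
    def tissue_mask(self) -> np.ndarray:
        """All voxels with any signal (brain plus extracerebral tissue)."""
        return (self.K1_map > 0) | (self.VA_map > 0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class DynamicImage:
    """4D dynamic PET: one 3D activity volume (kBq/mL) per frame."""

    data: np.ndarray  # (nx, ny, nz, n_frames)
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, frame)")
        if self.data.shape[-1] != self.schedule.n_frames:
            raise ValueError("number of volumes must equal number of frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("activity must be finite")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")


def _ellipsoid_mask(shape, voxel_size, semi_axes_mm) -> np.ndarray:
    """Voxel-center inclusion mask of an ellipsoid centred in the grid."""
    x, y, z = [
        ((np.arange(n) + 0.5) * v - n * v / 2.0).reshape(
            [-1 if i == ax else 1 for i in range(3)]
        )
        for ax, (n, v) in enumerate(zip(shape, voxel_size))
    ]
    a, b, c = semi_axes_mm
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def make_brain_phantom(
    shape: tuple[int, int, int] = (64, 64, 40),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    gm_params: TissueParams = DEFAULT_GM,
    wm_params: TissueParams = DEFAULT_WM,
    gm_volume_cm3: float = 330.0,
    wm_volume_cm3: float = 220.0,
    deep_gm_volume_cm3: float = 80.0,
    scalp_params: TissueParams = DEFAULT_SCALP,
    scalp_thickness_mm: float = 8.0,
    within_tissue_cv: float = 0.0,
    seed: int | None = None,
) -> BrainPhantom:
    """Build a concentric-shell brain phantom.

    From inside out: a deep grey-matter core (thalamus/basal-ganglia
    analogue), a white-matter shell, a cortical grey-matter shell, and an
    optional low-perfusion extracerebral (scalp) layer.  All ellipsoids
    share the grid's aspect ratio and are scaled so the realized volumes
    match the requests (within a voxel shell).

    The deep core matters for the partial-volume physics: with WM arranged
    as a shell of roughly 15 mm thickness, its deepest voxels — the ones the
    CWM VOI selects — lie within a centimetre of grey matter on both sides,
    as the centrum semiovale does in a real head.  A solid WM core would put
    them tens of millimetres from any grey matter, out of reach of any
    realistic point-spread function.  ``deep_gm_volume_cm3`` counts toward
    the total GM volume.  The scalp layer is not part of any brain mask; it
    keeps the brain boundary from being an artificial tissue/air cliff.

    ``within_tissue_cv`` adds seeded lognormal variation of K1 per voxel
    (k2 follows through the fixed per-tissue VT).
    """
    shape = tuple(int(s) for s in shape)
    extent = np.array(shape) * np.array(voxel_size)  # mm
    if not 0.0 <= deep_gm_volume_cm3 < gm_volume_cm3:
        raise ValueError("deep_gm_volume_cm3 must be in [0, gm_volume_cm3)")
    total_mm3 = (gm_volume_cm3 + wm_volume_cm3) * 1e3
    core_mm3 = deep_gm_volume_cm3 * 1e3
    wm_outer_mm3 = (deep_gm_volume_cm3 + wm_volume_cm3) * 1e3
    if wm_volume_cm3 < 20.0:
        warnings.warn(
            "requested WM volume below 20 cm3: downstream CWM extraction ill-posed"
        )
    # Largest ellipsoid with the grid's aspect, then scale to requested volume.
    base = extent / 2.0 * 0.95
    base_vol = 4.0 / 3.0 * np.pi * np.prod(base)
    if total_mm3 > base_vol:
        raise ValueError("requested GM+WM volume does not fit inside the grid")
    outer = base * (total_mm3 / base_vol) ** (1.0 / 3.0)
    wm_outer = base * (wm_outer_mm3 / base_vol) ** (1.0 / 3.0)
    core = base * (core_mm3 / base_vol) ** (1.0 / 3.0)

    brain = _ellipsoid_mask(shape, voxel_size, outer)
    wm_ell = _ellipsoid_mask(shape, voxel_size, wm_outer)
    core_mask = (
        _ellipsoid_mask(shape, voxel_size, core)
        if deep_gm_volume_cm3 > 0
        else np.zeros(shape, dtype=bool)
    )
    wm = wm_ell & ~core_mask
    gm = (brain & ~wm_ell) | core_mask
    if not gm.any() or not wm.any():
        raise ValueError("degenerate geometry: empty GM or WM mask")
    scalp = np.zeros(shape, dtype=bool)
    if scalp_thickness_mm > 0:
        scalp_semi = np.minimum(outer + scalp_thickness_mm, extent / 2.0)
        scalp = _ellipsoid_mask(shape, voxel_size, scalp_semi) & ~brain

    K1 = np.zeros(shape, dtype=np.float32)
    k2 = np.zeros(shape, dtype=np.float32)
    VA = np.zeros(shape, dtype=np.float32)
    rng = np.random.default_rng(seed)
    for mask, p in ((gm, gm_params), (wm, wm_params), (scalp, scalp_params)):
        if not mask.any():
            continue
        k1_val = np.full(int(mask.sum()), p.K1)
        if within_tissue_cv > 0:
            sigma = np.sqrt(np.log(1.0 + within_tissue_cv**2))
            k1_val = k1_val * rng.lognormal(-0.5 * sigma**2, sigma, size=k1_val.size)
        K1[mask] = k1_val
        k2[mask] = k1_val / p.VT
        VA[mask] = p.VA
    return BrainPhantom(
        gm_mask=gm, wm_mask=wm, K1_map=K1, k2_map=k2, VA_map=VA, voxel_size=voxel_size
    )


def simulate_dynamic_pet(
    phantom: BrainPhantom,
    aif,
    schedule: FrameSchedule | None = None,
    effective_fwhm: float = 0.0,
    noise_scale: float = 2.0,
    seed: int | None = None,
) -> DynamicImage:
    """Simulate frame-integrated dynamic PET at a given effective resolution.

    Per voxel, the noise-free TAC is the frame-averaged one-tissue model
    prediction from the voxel's true parameters; each frame is then blurred
    with a 3D Gaussian of FWHM ``effective_fwhm`` (mm), and zero-mean
    Gaussian noise with standard deviation
    ``noise_scale * sqrt(activity / frame_duration)`` is added, emulating
    the count-statistics scaling of reconstructed-PET noise.
    """
    if schedule is None:
        schedule = FrameSchedule.default()
    if effective_fwhm < 0 or noise_scale < 0:
        raise ValueError("effective_fwhm and noise_scale must be >= 0")
    if schedule.ends[-1] > aif.times[-1] + 1e-9:
        raise ValueError("schedule extends beyond the AIF support")

    grid = aif.times
    activity = aif.activity
    A = frame_average(grid, activity, schedule).values

    shape = phantom.gm_mask.shape
    nf = schedule.n_frames
    data = np.zeros(shape + (nf,), dtype=np.float32)

    tissue = phantom.tissue_mask
    k2_vox = phantom.k2_map[tissue]
    k1_vox = phantom.K1_map[tissue]
    va_vox = phantom.VA_map[tissue]

    # The model is linear in K1 and VA given k2; only distinct k2 values need
    # a convolution.  Quantize when within-tissue variation makes them many.
    uniq, inv = np.unique(np.round(k2_vox, 4), return_inverse=True)
    if uniq.size > 64:
        edges = np.quantile(k2_vox, np.linspace(0, 1, 65))
        centers = 0.5 * (edges[1:] + edges[:-1])
        inv = np.clip(np.searchsorted(edges, k2_vox) - 1, 0, 63)
        uniq = centers
    basis = np.empty((uniq.size, nf))
    for i, k2 in enumerate(uniq):
        conv = expconv(grid, activity, float(k2) / SEC_PER_MIN)
        basis[i] = frame_average(grid, conv, schedule).values

    tacs = (
        (1.0 - va_vox)[:, None] * (k1_vox / SEC_PER_MIN)[:, None] * basis[inv]
        + va_vox[:, None] * A[None, :]
    )
    data[tissue] = tacs.astype(np.float32)

    if effective_fwhm > 0:
        sigma_vox = [
            effective_fwhm * FWHM_TO_SIGMA / v for v in phantom.voxel_size
        ]
        for f in range(nf):
            data[..., f] = gaussian_filter(data[..., f], sigma=sigma_vox)

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(
            np.clip(data, 0.0, None) / schedule.durations[None, None, None, :]
        )
        data = data + rng.standard_normal(data.shape).astype(np.float32) * sd.astype(
            np.float32
        )
    return DynamicImage(data=data, schedule=schedule, voxel_size=phantom.voxel_size)


@dataclass
class NemaPhantom:
    """Digital NEMA image-quality phantom.

    Six fillable spheres (internal diameters 10–37 mm) on a 57.2 mm ring in
    the central transaxial slice of a ~9.7 L elliptical-cylinder body.
    Coordinates are mm relative to the volume centre; voxels belong to a
    sphere if their centre lies inside the radius.
    """

    volume: np.ndarray  # 3D activity, kBq/mL
    sphere_centers: np.ndarray  # (6, 3) mm
    sphere_diameters: tuple[float, ...]
    sphere_activity: float
    background_activity: float
    voxel_size: float  # mm, isotropic

    def coords(self):
        """Voxel-centre coordinate grids (mm, volume-centred)."""
        return [
            (np.arange(n) + 0.5) * self.voxel_size - n * self.voxel_size / 2.0
            for n in self.volume.shape
        ]

    def sphere_mask(self, index: int) -> np.ndarray:
        cx, cy, cz = self.sphere_centers[index]
        r = self.sphere_diameters[index] / 2.0
        xs, ys, zs = self.coords()
        x = xs.reshape(-1, 1, 1)
        y = ys.reshape(1, -1, 1)
        z = zs.reshape(1, 1, -1)
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2

    def fingerprint(self) -> tuple:
        """Hashable key for library caching."""
        return (
            self.volume.shape,
            self.voxel_size,
            self.sphere_activity,
            self.background_activity,
            tuple(self.sphere_diameters),
            tuple(map(tuple, np.round(self.sphere_centers, 6))),
        )


def make_nema_phantom(voxel_size: float = 1.0) -> NemaPhantom:
    """Build the digital NEMA IQ phantom at an isotropic voxel size (mm).

    The body is a 9.7 L elliptical cylinder (semi-axes 150 x 115 mm, length
    180 mm) at background activity 2.2 kBq/mL; the six spheres sit at
    22.3 kBq/mL on a 57.2 mm ring in the central slice.  The lung insert is
    omitted: recovery analysis uses only sphere interiors and nearby
    background.
    """
    if voxel_size > 2.0:
        raise ValueError("voxel_size must be <= 2 mm to resolve the 10 mm sphere")
    a, b, half_len = 150.0, 115.0, 90.0  # mm
    margin = 10.0
    shape = tuple(
        int(np.ceil(2 * (v + margin) / voxel_size)) for v in (a, b, half_len)
    )
    xs, ys, zs = [
        (np.arange(n) + 0.5) * voxel_size - n * voxel_size / 2.0 for n in shape
    ]
    x = xs.reshape(-1, 1, 1)
    y = ys.reshape(1, -1, 1)
    z = zs.reshape(1, 1, -1)
    body = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (np.abs(z) <= half_len)
    volume = np.where(body, NEMA_BACKGROUND_ACTIVITY, 0.0).astype(np.float32)

    angles = np.deg2rad(np.arange(6) * 60.0)
    centers = np.stack(
        [
            NEMA_RING_RADIUS * np.cos(angles),
            NEMA_RING_RADIUS * np.sin(angles),
            np.zeros(6),
        ],
        axis=1,
    )
    for (cx, cy, cz), d in zip(centers, NEMA_SPHERE_DIAMETERS):
        r = d / 2.0
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        volume[inside] = NEMA_SPHERE_ACTIVITY
    return NemaPhantom(
        volume=volume,
        sphere_centers=centers,
        sphere_diameters=NEMA_SPHERE_DIAMETERS,
        sphere_activity=NEMA_SPHERE_ACTIVITY,
        background_activity=NEMA_BACKGROUND_ACTIVITY,
        voxel_size=float(voxel_size),
    )
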