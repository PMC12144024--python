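"""Volumes of interest: whole brain, grey matter, and central white matter.

The whole-brain (WB) VOI is the union of the grey- and white-matter masks.
The central white matter (CWM) VOI emulates a centrum semiovale region: the
binary WM mask is smoothed with a 7 mm Gaussian and the 20 cm3 of WM voxels
with the highest smoothed values — the deepest white matter, farthest from
grey matter spill-over — are selected.  Selection is exact top-N with a
fixed voxel ordering, so the realized volume is within one voxel of the
target and the construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import FrameSchedule
from .kinetics import TimeActivityCurve
from .synth import FWHM_TO_SIGMA, DynamicImage

__all__ = ["VoiMask", "build_wb", "build_cwm", "extract_tac"]


@dataclass(frozen=True)
class VoiMask:
    """A labelled boolean volume of interest."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1e3


def _check_same_grid(a: VoiMask, b: VoiMask) -> None:
    if a.mask.shape != b.mask.shape or not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError("masks are not on the same grid")


def build_wb(gm: VoiMask, wm: VoiMask) -> VoiMask:
    """Whole-brain VOI as the union of the GM and WM masks."""
    _check_same_grid(gm, wm)
    return VoiMask(gm.mask | wm.mask, gm.voxel_size, label="WB")


def build_cwm(
    wm: VoiMask, smoothing_fwhm: float = 7.0, target_volume_cm3: float = 20.0
) -> VoiMask:
    """Central white matter VOI by smoothing and adaptive thresholding.

    The WM mask is smoothed with a Gaussian of FWHM ``smoothing_fwhm`` (mm,
    per-axis sigma in voxel units for anisotropic voxels) and the N WM
    voxels with the highest smoothed value are selected, where N matches
    ``target_volume_cm3``.  Ties are broken by flat voxel order (stable
    sort), so the result is deterministic.
    """
    if wm.volume_cm3 <= target_volume_cm3:
        raise ValueError("WM volume must exceed the CWM target volume")
    n_target = int(round(target_volume_cm3 * 1e3 / wm.voxel_volume_mm3))
    sigma_vox = [smoothing_fwhm * FWHM_TO_SIGMA / v for v in wm.voxel_size]
    smoothed = gaussian_filter(wm.mask.astype(float), sigma=sigma_vox)

    flat = smoothed.ravel()
    wm_idx = np.flatnonzero(wm.mask.ravel())
    # Deep inside a large WM mask the smoothed field plateaus at exactly 1,
    # so ties are common; break them toward the WM centroid (deep white),
    # then by flat index, keeping the selection deterministic and centred.
    coords = np.argwhere(wm.mask) * np.asarray(wm.voxel_size)
    centroid = coords.mean(axis=0)
    dist2 = ((coords - centroid) ** 2).sum(axis=1)
    order = wm_idx[np.lexsort((wm_idx, dist2, -flat[wm_idx]))]
    selected = order[:n_target]
    out = np.zeros(wm.mask.size, dtype=bool)
    out[selected] = True
    return VoiMask(out.reshape(wm.mask.shape), wm.voxel_size, label="CWM")


def extract_tac(dynamic: DynamicImage, voi: VoiMask) -> TimeActivityCurve:
    """Per-frame unweighted mean of the dynamic image inside the mask."""
    if voi.mask.shape != dynamic.data.shape[:3]:
        raise ValueError("VOI grid does not match the dynamic image")
    if not voi.mask.any():
        raise ValueError("empty VOI mask")
    values = dynamic.data[voi.mask].mean(axis=0)
    return TimeActivityCurve(dynamic.schedule, np.asarray(values, dtype=float))
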