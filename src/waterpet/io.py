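"""NIfTI reading/writing for dynamic images, masks, and parameter maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .frames import FrameSchedule
from .kinetics import ParametricMaps
from .synth import DynamicImage
from .voi import VoiMask

__all__ = [
    "save_volume",
    "load_volume",
    "save_dynamic",
    "load_dynamic",
    "save_mask",
    "load_mask",
    "save_parametric_maps",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_volume(data: np.ndarray, voxel_size, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size)), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float32), vox


def save_dynamic(dynamic: DynamicImage, path: str | Path) -> None:
    """Write a 4D dynamic image; the frame schedule goes to a JSON sidecar."""
    save_volume(dynamic.data, dynamic.voxel_size, path)
    dynamic.schedule.to_json(Path(path).with_suffix("").with_suffix(".json"))


def load_dynamic(path: str | Path) -> DynamicImage:
    data, vox = load_volume(path)
    schedule = FrameSchedule.from_json(Path(path).with_suffix("").with_suffix(".json"))
    return DynamicImage(data=data, schedule=schedule, voxel_size=vox)


def save_mask(voi: VoiMask, path: str | Path) -> None:
    save_volume(voi.mask.astype(np.uint8), voi.voxel_size, path)


def load_mask(path: str | Path, label: str = "custom") -> VoiMask:
    data, vox = load_volume(path)
    return VoiMask(data > 0.5, vox, label=label)


def save_parametric_maps(
    maps: ParametricMaps, voxel_size, out_dir: str | Path, prefix: str = ""
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, data in (
        ("K1", maps.K1_map),
        ("k2", maps.k2_map),
        ("VA", maps.VA_map),
        ("VT", maps.VT_map),
    ):
        save_volume(data, voxel_size, out / f"{prefix}{name}.nii")
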