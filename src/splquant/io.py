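"""NIfTI and sidecar I/O for diffusion stacks, SUV volumes and ROI masks."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .diffusion_models import BValueProtocol, DiffusionVolumeStack, ParameterMap
from .pet_metrics import LesionROI, SUVVolume

__all__ = [
    "save_stack",
    "load_stack",
    "save_suv_volume",
    "load_suv_volume",
    "save_mask",
    "load_mask",
    "save_parameter_map",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def _voxel_size(img: nib.Nifti1Image) -> tuple[float, ...]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def save_stack(stack: DiffusionVolumeStack, nii_path, bvals_path=None) -> None:
    """Write a 4D stack as NIfTI plus a {"bvalues": [...]} sidecar JSON."""
    nii_path = Path(nii_path)
    nib.save(
        nib.Nifti1Image(stack.data.astype(np.float64), _affine(stack.voxel_size)),
        str(nii_path),
    )
    if bvals_path is None:
        base = nii_path.name.removesuffix(".gz").removesuffix(".nii")
        bvals_path = nii_path.with_name(base + "_bvalues.json")
    Path(bvals_path).write_text(json.dumps({"bvalues": list(stack.protocol.bvalues)}))


def load_stack(nii_path, bvals_path) -> DiffusionVolumeStack:
    img = nib.load(str(nii_path))
    with open(bvals_path) as fh:
        bvalues = json.load(fh)["bvalues"]
    return DiffusionVolumeStack(
        data=np.asarray(img.get_fdata(), dtype=float),
        protocol=BValueProtocol(bvalues),
        voxel_size=_voxel_size(img),
    )


def save_suv_volume(vol: SUVVolume, path, voxel_size=None) -> None:
    if voxel_size is None:
        side = vol.voxel_volume ** (1.0 / 3.0)  # isotropic unless told otherwise
        voxel_size = (side, side, side)
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), _affine(voxel_size)), str(path))


def load_suv_volume(path) -> SUVVolume:
    img = nib.load(str(path))
    vox = _voxel_size(img)
    return SUVVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        voxel_volume=float(np.prod(vox)),
    )


def save_mask(mask: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size)), str(path)
    )


def load_mask(path) -> LesionROI:
    img = nib.load(str(path))
    return LesionROI(mask=np.asarray(img.get_fdata()) > 0.5, provenance="manual")


def save_parameter_map(pmap: ParameterMap, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    nib.save(
        nib.Nifti1Image(pmap.values.astype(np.float64), _affine(voxel_size)), str(path)
    )
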