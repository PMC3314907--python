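"""NIfTI / bval / bvec dataset I/O and map writing.

Conventions, stated loudly because nothing in the file formats enforces
them: gradient directions follow the FSL dialect (bvec columns live in the
image coordinate frame) and are rotated into world coordinates by the
rotation part of the NIfTI affine before any physics is done; all spatial
modelling runs in world mm derived from the affine, never in voxel indices,
because perturbation fields are fixed in the scanner frame.  Tensor fields
are stored as 6-volume NIfTI in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), recorded in the header description.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.linalg import polar

from .gradients import GradientScheme, read_bval_bvec
from .tensor import DiffusionTensorField
from .gradients import lower_tri_to_tensors, tensors_to_lower_tri

__all__ = [
    "read_dwi_bundle",
    "write_dwi_bundle",
    "write_maps",
    "write_tensor_field",
    "read_tensor_field",
]

TENSOR_ORDER_NOTE = "tensor lower-tri order: Dxx Dxy Dyy Dxz Dyz Dzz"


def affine_rotation(affine: np.ndarray) -> np.ndarray:
    """Pure rotation part of a voxel->world affine (polar decomposition)."""
    r, _ = polar(np.asarray(affine, dtype=float)[:3, :3])
    return r


def read_dwi_bundle(dwi_path, bval_path, bvec_path, mask_path=None):
    """Load a DWI dataset with its gradient scheme.

    Returns (volumes, scheme, affine[, mask]).  Directions are rotated to
    world coordinates; the volume count must match the scheme length.
    """
    dwi_path = Path(dwi_path)
    if not dwi_path.exists():
        raise FileNotFoundError(f"DWI file not found: {dwi_path}")
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D DWI, got shape {data.shape}")
    scheme = read_bval_bvec(bval_path, bvec_path)
    if scheme.n_volumes != data.shape[3]:
        raise ValueError(
            f"DWI has {data.shape[3]} volumes but gradient scheme has "
            f"{scheme.n_volumes} entries ({bval_path})"
        )
    affine = img.affine
    rot = affine_rotation(affine)
    scheme = GradientScheme(
        b_values=scheme.b_values, directions=scheme.directions @ rot.T
    )
    if mask_path is None:
        return data, scheme, affine
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    return data, scheme, affine, mask


def write_dwi_bundle(dwi, scheme: GradientScheme, affine, prefix) -> dict:
    """Write <prefix>dwi.nii.gz plus FSL bval/bvec files."""
    from .gradients import write_bval_bvec

    prefix = str(prefix)
    paths = {
        "dwi": prefix + "dwi.nii.gz",
        "bval": prefix + "dwi.bval",
        "bvec": prefix + "dwi.bvec",
    }
    nib.save(nib.Nifti1Image(np.asarray(dwi, dtype=np.float32), affine), paths["dwi"])
    # store bvecs back in the image frame (FSL dialect)
    rot = affine_rotation(affine)
    image_frame = GradientScheme(
        b_values=scheme.b_values, directions=scheme.directions @ rot
    )
    write_bval_bvec(image_frame, paths["bval"], paths["bvec"])
    return paths


def write_maps(maps: dict, affine, prefix, report: dict | None = None) -> dict:
    """Write scalar maps as NIfTI and an optional JSON report.

    maps: name -> 3-D array.  Returns the written paths.
    """
    prefix = str(prefix)
    paths = {}
    for name, vol in maps.items():
        p = f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), p)
        paths[name] = p
    if report is not None:
        p = f"{prefix}report.json"
        Path(p).write_text(json.dumps(report, indent=1, sort_keys=True))
        paths["report"] = p
    return paths


def write_tensor_field(field: DiffusionTensorField, path) -> None:
    """Tensor field as 6-volume NIfTI, lower-triangular component order."""
    vols = tensors_to_lower_tri(field.tensors).astype(np.float32)
    img = nib.Nifti1Image(vols, field.affine)
    img.header["descrip"] = TENSOR_ORDER_NOTE.encode()[:79]
    nib.save(img, str(path))


def read_tensor_field(path) -> DiffusionTensorField:
    img = nib.load(str(path))
    vols = np.asarray(img.dataobj, dtype=float)
    if vols.ndim != 4 or vols.shape[3] != 6:
        raise ValueError(f"expected a 6-volume tensor NIfTI, got shape {vols.shape}")
    tensors = lower_tri_to_tensors(vols)
    mask = np.all(np.isfinite(vols), axis=-1) & np.any(vols != 0, axis=-1)
    return DiffusionTensorField(tensors=tensors, affine=img.affine, mask=mask)
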