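"""ADC computation, diffusion tensor fitting and scalar index maps.

The tensor model relates the apparent diffusion coefficient along direction i
to the symmetric 3x3 diffusion tensor D through the double contraction
ADC_i = B_i : D.  Fitting inverts this linear relation over >= 6 non-collinear
directions; scalar indices (MD, FA, eigensystem) follow the standard
definitions of the DTI literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .gradients import (
    GradientScheme,
    b_matrices,
    lower_tri_to_tensors,
    tensor_design_matrix,
    tensors_to_lower_tri,
)

__all__ = [
    "adc_from_signals",
    "adc_volumes",
    "fit_tensor",
    "fit_tensor_field",
    "tensor_indices",
    "TensorIndices",
    "DiffusionTensorField",
]


def adc_from_signals(s0, s_dw, b):
    """Apparent diffusion coefficient ln(s0 / s_dw) / b in mm^2/s.

    Non-positive signals yield NaN (flagged invalid, to be excluded from
    fits) rather than raising, so whole-volume calls survive noise.
    """
    s0 = np.asarray(s0, dtype=float)
    s_dw = np.asarray(s_dw, dtype=float)
    if np.any(np.asarray(b) <= 0):
        raise ValueError("ADC requires b > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((s0 > 0) & (s_dw > 0), s0 / np.where(s_dw > 0, s_dw, 1.0), np.nan)
        return np.log(ratio) / b


def adc_volumes(dwi: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Per-direction ADC volumes from a 4-D DWI array.

    The b=0 reference is the mean of all b=0 volumes.  Returns an array of
    shape grid + (n_dw,), NaN where signals are invalid.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI has {dwi.shape[-1]} volumes but scheme has {scheme.n_volumes}"
        )
    s0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    dw = dwi[..., scheme.dw_mask]
    b = scheme.b_values[scheme.dw_mask]
    return adc_from_signals(s0[..., None], dw, b)


def _adc_design(bmats: np.ndarray) -> np.ndarray:
    """Design matrix for ADC data: rows from the unit-trace-normalized B/b.

    ADC = ln(S0/S)/b carries the b-value division already, so the design
    contracting with D must use B/b = g g^T (for a Stejskal-Tanner direction
    trace(B) = b).
    """
    bmats = np.asarray(bmats, dtype=float)
    b = np.trace(bmats, axis1=-2, axis2=-1)
    if np.any(b <= 0):
        raise ValueError("ADC fitting requires b > 0 for every row")
    return tensor_design_matrix(bmats / b[..., None, None])


def fit_tensor(adcs: np.ndarray, bmats: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Least-squares fit of a symmetric tensor D to per-direction ADCs.

    The ADC along direction i contracts with the unit-trace-normalized B
    matrix: ADC_i = (B_i / b_i) : D = g_i^T D g_i.  Ordinary least squares
    by default; optional per-direction weights.  Exact when the linear
    system is consistent.
    """
    adcs = np.asarray(adcs, dtype=float)
    design = _adc_design(bmats)
    if design.shape[0] < 6:
        raise ValueError(f"need >= 6 directions, got {design.shape[0]}")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        design = design * w[:, None]
        adcs = adcs * w
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError(
            "rank-deficient design: gradient directions do not span the "
            "6-dimensional space of symmetric tensors"
        )
    coef, *_ = np.linalg.lstsq(design, adcs, rcond=None)
    return lower_tri_to_tensors(coef)


def fit_tensor_field(
    adcs: np.ndarray, scheme: GradientScheme, return_residual_var: bool = False
):
    """Vectorized OLS tensor fit over an (..., n_dw) ADC array.

    Voxels containing NaN ADCs produce NaN tensors.  Optionally returns the
    per-voxel residual variance of the fit (sum of squared residuals divided
    by n_dw - 6), the natural artefact/noise proxy for later weighting.
    """
    scheme.validate_for_tensor_fit()
    design = _adc_design(b_matrices(scheme)[scheme.dw_mask])
    pinv = np.linalg.pinv(design)
    adcs = np.asarray(adcs, dtype=float)
    coef = adcs @ pinv.T
    tensors = lower_tri_to_tensors(coef)
    if not return_residual_var:
        return tensors
    resid = adcs - coef @ design.T
    dof = max(design.shape[0] - 6, 1)
    res_var = np.sum(resid**2, axis=-1) / dof
    return tensors, res_var


class TensorIndices(NamedTuple):
    md: np.ndarray
    fa: np.ndarray
    trace: np.ndarray
    eigenvalues: np.ndarray      # sorted descending, (..., 3)
    principal_axis: np.ndarray   # (..., 3), first nonzero component positive


def tensor_indices(d: np.ndarray) -> TensorIndices:
    """MD, FA, trace, eigenvalues and principal axis of symmetric tensors.

    FA = sqrt(3/2) * ||D - MD I||_F / ||D||_F, defined as 0 for the zero
    tensor.  Eigenvalues are sorted descending; the principal axis sign is
    fixed so its first nonzero component is positive.  Works on arrays of
    tensors of shape (..., 3, 3).
    """
    d = np.asarray(d, dtype=float)
    tr = np.trace(d, axis1=-2, axis2=-1)
    md = tr / 3.0
    dev = d - md[..., None, None] * np.eye(3)
    norm_d = np.linalg.norm(d, axis=(-2, -1))
    norm_dev = np.linalg.norm(dev, axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(norm_d > 0, norm_dev / np.where(norm_d > 0, norm_d, 1.0), 0.0)
    # eigh is ascending; flip to descending
    finite = np.all(np.isfinite(d), axis=(-2, -1))
    d_safe = np.where(finite[..., None, None], d, np.eye(3))
    evals, evecs = np.linalg.eigh(d_safe)
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    e1 = evecs[..., :, 0]
    # sign convention: scan x, y, z and flip so the first component whose
    # magnitude exceeds 1e-12 is positive
    chosen = np.zeros(e1.shape[:-1])
    decided = np.zeros(e1.shape[:-1], dtype=bool)
    for k in range(3):
        comp = e1[..., k]
        take = (~decided) & (np.abs(comp) > 1e-12)
        chosen = np.where(take, np.sign(comp), chosen)
        decided |= take
    chosen = np.where(decided, chosen, 1.0)
    e1 = e1 * chosen[..., None]
    evals = np.where(finite[..., None], evals, np.nan)
    e1 = np.where(finite[..., None], e1, np.nan)
    return TensorIndices(md=md, fa=fa, trace=tr, eigenvalues=evals, principal_axis=e1)


@dataclass
class DiffusionTensorField:
    """Voxel grid of symmetric 3x3 tensors with a voxel->world affine.

    tensors has shape grid + (3, 3) in mm^2/s; mask marks valid voxels;
    residual_var optionally carries the per-voxel fit residual variance.
    """

    tensors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    residual_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.mask.shape != self.tensors.shape[:-2]:
            raise ValueError("mask shape does not match tensor grid")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple:
        return self.tensors.shape[:-2]

    def indices(self) -> TensorIndices:
        return tensor_indices(self.tensors)
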