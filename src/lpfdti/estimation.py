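"""Two-step estimation of the perturbation field from water-phantom DWI.

A water phantom diffuses isotropically with a single coefficient D_w, so any
anisotropy or spatial structure in its fitted tensors is instrument bias:
under the linear perturbation model the voxelwise fitted tensor equals
D_w * L(r) with L = I + 2 Sigma+.  Step 1 therefore fits a standard tensor
per voxel; step 2 divides by D_w, converts to Sigma+ and fits each of the six
unique elements with a 3rd-order solid-harmonic expansion by weighted least
squares, down-weighting voxels with large tensor-fit residual variance
(vibration, ghosting and other non-gradient artefacts raise the residual but
do not correlate with gradient direction, so they add noise rather than bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .gradients import GradientScheme
from .lpf import sigma_sym_from_ellipsoid, sym_part
from .shharm import SHCoefficients, evaluate_field, sh_design_matrix, wls_fit
from .tensor import DiffusionTensorField, adc_volumes, fit_tensor_field

__all__ = [
    "LPFModel",
    "grid_world_coords",
    "auto_phantom_mask",
    "voxelwise_ellipsoid",
    "estimate_dw",
    "fit_lpf_field",
    "evaluate_lpf",
    "estimate_lpf_model",
]

# unique elements of a symmetric 3x3 matrix, lower-triangular order
SIGMA_ELEMENTS = ("xx", "xy", "yy", "xz", "yz", "zz")
_ELEM_IDX = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


def grid_world_coords(shape: tuple, affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel centre, shape grid + (3,)."""
    idx = np.indices(shape, dtype=float)
    ones = np.ones(shape)
    hom = np.stack([idx[0], idx[1], idx[2], ones], axis=-1)
    return hom @ np.asarray(affine, dtype=float).T[:, :3]


@dataclass
class LPFModel:
    """Six solid-harmonic expansions, one per unique element of Sigma+.

    All six share order and frame.  d_w is the water diffusion coefficient
    (mm^2/s) used to normalize the phantom tensors; metadata carries
    provenance (mask size, residual statistics, source file).
    """

    elements: dict[str, SHCoefficients]
    d_w: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.elements) != set(SIGMA_ELEMENTS):
            raise ValueError(f"elements must be exactly {SIGMA_ELEMENTS}")
        ref = self.elements["xx"]
        for name, c in self.elements.items():
            if not ref.same_frame(c):
                raise ValueError(f"element {name} is in a different frame/order")
        if self.d_w <= 0:
            raise ValueError("d_w must be positive")

    @property
    def order(self) -> int:
        return self.elements["xx"].order

    @property
    def origin_mm(self) -> np.ndarray:
        return self.elements["xx"].origin_mm

    @property
    def r_ref_mm(self) -> float:
        return self.elements["xx"].r_ref_mm

    def sigma_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Symmetric Sigma+ matrices at world-mm points, shape (..., 3, 3)."""
        points_mm = np.asarray(points_mm, dtype=float)
        lead = points_mm.shape[:-1]
        flat = points_mm.reshape(-1, 3)
        design = sh_design_matrix(
            flat, self.order, origin_mm=self.origin_mm, r_ref_mm=self.r_ref_mm
        )
        out = np.zeros((flat.shape[0], 3, 3))
        for name, (i, j) in zip(SIGMA_ELEMENTS, _ELEM_IDX):
            vals = design @ self.elements[name].coefficients
            out[:, i, j] = vals
            out[:, j, i] = vals
        return out.reshape(lead + (3, 3))

    def to_dict(self) -> dict:
        return {
            "model": "local-perturbation-field, symmetric part, solid-harmonic expansion",
            "d_w_mm2_per_s": self.d_w,
            "elements": {k: v.to_dict() for k, v in self.elements.items()},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPFModel":
        return cls(
            elements={k: SHCoefficients.from_dict(v) for k, v in d["elements"].items()},
            d_w=float(d["d_w_mm2_per_s"]),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LPFModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def auto_phantom_mask(dwi: np.ndarray, scheme: GradientScheme, erode: int = 2) -> np.ndarray:
    """Phantom mask: 30% of the robust maximum of the mean b=0 image, eroded.

    The robust maximum is the 99th percentile (guards against hot pixels);
    erosion by 2 voxels drops edge voxels where partial volume and smoothing
    ringing violate the smooth-field assumption.
    """
    b0 = np.asarray(dwi, dtype=float)[..., scheme.b0_mask].mean(axis=-1)
    robust_max = np.percentile(b0, 99)
    mask = b0 > 0.3 * robust_max
    if erode > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode)
    return mask


def voxelwise_ellipsoid(
    phantom_dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    affine: np.ndarray,
) -> DiffusionTensorField:
    """Step 1: per-voxel tensor fit of phantom ADCs.

    Under the model the fitted tensor equals D_w * L(r), i.e. the ellipsoid
    scaled by the (unknown) water diffusion coefficient.  Voxels with any
    invalid (non-positive) signal are dropped from the mask.  The returned
    field carries the per-voxel residual variance of the fit.
    """
    adcs = adc_volumes(phantom_dwi, scheme)
    valid = np.all(np.isfinite(adcs), axis=-1)
    mask = np.asarray(mask, dtype=bool) & valid
    tensors = np.full(mask.shape + (3, 3), np.nan)
    res_var = np.full(mask.shape, np.nan)
    t, rv = fit_tensor_field(adcs[mask], scheme, return_residual_var=True)
    tensors[mask] = t
    res_var[mask] = rv
    return DiffusionTensorField(tensors=tensors, affine=affine, mask=mask, residual_var=res_var)


def estimate_dw(
    raw: DiffusionTensorField,
    roi_radius_mm: float = 15.0,
    override: float | None = None,
) -> float:
    """Water diffusion coefficient from the phantom centre.

    Median of trace/3 of the raw fitted tensors over a central sphere (the
    perturbation field is smallest near the isocentre, and the median is
    robust to corrupted voxels).  A user-supplied value (e.g. from the known
    phantom temperature) passes through untouched.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("D_w override must be positive")
        return float(override)
    coords = grid_world_coords(raw.shape, raw.affine)
    r = np.linalg.norm(coords, axis=-1)
    roi = raw.mask & (r <= roi_radius_mm)
    if np.sum(roi) < 10:
        raise ValueError(
            f"central ROI (radius {roi_radius_mm} mm) holds {int(np.sum(roi))} "
            "valid voxels; need >= 10"
        )
    md = np.trace(raw.tensors[roi], axis1=-2, axis2=-1) / 3.0
    return float(np.median(md))


def fit_lpf_field(
    ellipsoid_raw: DiffusionTensorField,
    d_w: float,
    order: int = 3,
    r_ref_mm: float = 150.0,
    weights: str | np.ndarray = "residual",
    eps: float = 1e-12,
) -> LPFModel:
    """Step 2: constrained spatial fit of the six Sigma+ elements.

    Converts the raw field to Sigma+ = (tensor / D_w - I) / 2 per voxel and
    fits each unique element with an order-3 solid-harmonic expansion by
    weighted least squares, weights 1 / (residual_var + eps) by default
    (pass weights="uniform" or an explicit per-voxel array to override).
    """
    if d_w <= 0:
        raise ValueError("d_w must be positive")
    mask = ellipsoid_raw.mask
    n = int(np.sum(mask))
    if n < (order + 1) ** 2:
        raise ValueError(f"{n} voxels cannot constrain {(order + 1) ** 2} coefficients")
    coords = grid_world_coords(ellipsoid_raw.shape, ellipsoid_raw.affine)[mask]
    span = np.ptp(coords, axis=0)
    if order >= 1 and np.any(span < 1e-9):
        raise ValueError(
            "spatial sampling is degenerate (single plane); cannot constrain "
            "a 3-D harmonic expansion"
        )
    if isinstance(weights, str):
        if weights == "residual":
            if ellipsoid_raw.residual_var is None:
                raise ValueError("field carries no residual variance; use weights='uniform'")
            w = 1.0 / (ellipsoid_raw.residual_var[mask] + eps)
        elif weights == "uniform":
            w = np.ones(n)
        else:
            raise ValueError(f"unknown weights mode {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape == mask.shape:
            w = w[mask]
    sigma = sigma_sym_from_ellipsoid(ellipsoid_raw.tensors[mask] / d_w)
    design = sh_design_matrix(coords, order, origin_mm=np.zeros(3), r_ref_mm=r_ref_mm)
    elements = {}
    residual_rms = {}
    for name, (i, j) in zip(SIGMA_ELEMENTS, _ELEM_IDX):
        vals = sigma[:, i, j]
        coef = wls_fit(design, vals, w)
        elements[name] = SHCoefficients(
            order=order, coefficients=coef, origin_mm=np.zeros(3), r_ref_mm=r_ref_mm
        )
        residual_rms[name] = float(np.sqrt(np.mean((design @ coef - vals) ** 2)))
    return LPFModel(
        elements=elements,
        d_w=d_w,
        metadata={"n_voxels": n, "fit_residual_rms": residual_rms},
    )


def evaluate_lpf(model: LPFModel, shape: tuple, affine: np.ndarray) -> np.ndarray:
    """Symmetric Sigma+(r) field on a voxel grid, shape grid + (3, 3).

    The field lives in the scanner (world) frame: coordinates come from the
    grid's affine, so evaluating the same model on a shifted grid yields the
    field at the shifted positions.
    """
    coords = grid_world_coords(shape, np.asarray(affine, dtype=float))
    return model.sigma_at(coords)


def estimate_lpf_model(
    phantom_dwi: np.ndarray,
    scheme: GradientScheme,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    d_w: float | None = None,
    order: int = 3,
    r_ref_mm: float = 150.0,
    dw_roi_radius_mm: float = 15.0,
) -> LPFModel:
    """Convenience wrapper running the full two-step phantom pipeline."""
    if mask is None:
        mask = auto_phantom_mask(phantom_dwi, scheme)
    raw = voxelwise_ellipsoid(phantom_dwi, scheme, mask, affine)
    d_w_val = estimate_dw(raw, roi_radius_mm=dw_roi_radius_mm, override=d_w)
    model = fit_lpf_field(raw, d_w_val, order=order, r_ref_mm=r_ref_mm)
    model.metadata["d_w_estimated"] = d_w is None
    return model
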