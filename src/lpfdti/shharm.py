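"""Real regular solid spherical harmonics and weighted least-squares fitting.

Gradient-coil fields are conventionally expanded in regular solid harmonics
r^l Y_lm(theta, phi) — harmonic polynomials in (x, y, z) — which can be
evaluated at arbitrary radius, unlike surface harmonics on a fixed sphere.
The basis here is the real (tesseral) form with the standard orthonormal
sphere normalization; coefficients are internal to the package, so only the
documented (l, m) ordering matters: l ascending, m = -l .. l, column 0 the
constant.  Coordinates are world mm relative to a stated origin (taken to be
the scanner isocentre) scaled by a reference radius R_ref for conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["SHCoefficients", "lm_ordering", "sh_design_matrix", "wls_fit", "evaluate_field"]


def lm_ordering(order: int) -> list[tuple[int, int]]:
    """(l, m) pairs in the package's column order."""
    return [(l, m) for l in range(order + 1) for m in range(-l, l + 1)]


def _real_solid_harmonics(xyz: np.ndarray, order: int) -> np.ndarray:
    """Evaluate real regular solid harmonics r^l Y_lm at dimensionless points."""
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, z / np.where(r > 0, r, 1.0), 1.0), -1, 1))
    phi = np.arctan2(y, x)
    cols = []
    for l, m in lm_ordering(order):
        if l == 0:
            cols.append(np.full(r.shape, float(sph_harm_y(0, 0, 0.0, 0.0).real)))
            continue
        ylm = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            ang = ylm.real
        elif m > 0:
            ang = np.sqrt(2.0) * (-1.0) ** m * ylm.real
        else:
            ang = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
        cols.append(r**l * ang)  # r^l * Y_lm -> polynomial, finite at r = 0
    return np.stack(cols, axis=-1)


@dataclass
class SHCoefficients:
    """One solid-harmonic expansion with its evaluation frame.

    coefficients: ((order+1)^2,) array, units of the expanded field
    (dimensionless for perturbation-matrix elements) per power of the scaled
    radius.  origin_mm / r_ref_mm define the frame: basis arguments are
    (world_mm - origin_mm) / r_ref_mm.
    """

    order: int
    coefficients: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_ref_mm: float = 150.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).ravel()
        if self.order < 0:
            raise ValueError("order must be >= 0")
        k = (self.order + 1) ** 2
        if self.coefficients.shape[0] != k:
            raise ValueError(
                f"order {self.order} needs {k} coefficients, got {self.coefficients.shape[0]}"
            )
        if self.r_ref_mm <= 0:
            raise ValueError("r_ref_mm must be positive")

    def same_frame(self, other: "SHCoefficients", tol: float = 1e-9) -> bool:
        return (
            self.order == other.order
            and abs(self.r_ref_mm - other.r_ref_mm) <= tol
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "frame": {"origin_mm": self.origin_mm.tolist(), "R_ref_mm": self.r_ref_mm},
            "lm_order": "l ascending 0..order, m=-l..l per l; column 0 constant",
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SHCoefficients":
        return cls(
            order=int(d["order"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            origin_mm=np.asarray(d["frame"]["origin_mm"], dtype=float),
            r_ref_mm=float(d["frame"]["R_ref_mm"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SHCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sh_design_matrix(
    points_mm: np.ndarray,
    order: int,
    origin_mm: np.ndarray | None = None,
    r_ref_mm: float = 150.0,
) -> np.ndarray:
    """N x (order+1)^2 design matrix of solid harmonics at world-mm points."""
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if not np.all(np.isfinite(points_mm)):
        raise ValueError("non-finite coordinates")
    if order < 0:
        raise ValueError("order must be >= 0")
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, dtype=float)
    u = (points_mm - origin) / float(r_ref_mm)
    return _real_solid_harmonics(u, order)


def wls_fit(design: np.ndarray, values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted least squares: minimize sum_i w_i (v_i - design_i . c)^2.

    Returns the coefficient vector.  Zero-weight rows are inert; a design
    left rank-deficient after weighting raises an error naming the deficient
    columns.
    """
    design = np.asarray(design, dtype=float)
    values = np.asarray(values, dtype=float)
    n, k = design.shape
    if n < k:
        raise ValueError(f"underdetermined: {n} points for {k} coefficients")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("all weights are zero")
        sw = np.sqrt(w)
        design = design * sw[:, None]
        values = values * sw
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        # name deficient columns via the magnitude of the trailing right
        # singular vectors
        _, _, vt = np.linalg.svd(design, full_matrices=False)
        null = vt[rank:]
        bad = np.flatnonzero(np.max(np.abs(null), axis=0) > 1e-6)
        raise ValueError(
            f"rank-deficient weighted design (rank {rank} < {k}); "
            f"deficient columns (l,m indices): {bad.tolist()}"
        )
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return coef


def evaluate_field(coeffs: SHCoefficients, points_mm: np.ndarray) -> np.ndarray:
    """Evaluate an expansion at world-mm points (linear in the coefficients)."""
    design = sh_design_matrix(
        points_mm, coeffs.order, origin_mm=coeffs.origin_mm, r_ref_mm=coeffs.r_ref_mm
    )
    return design @ coeffs.coefficients
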