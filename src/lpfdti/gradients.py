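"""Gradient schemes and B-matrix construction.

A diffusion acquisition is described per volume by a b-value (s/mm^2) and a
unit gradient direction g.  The B matrix of a Stejskal-Tanner direction is the
rank-one outer product B = b * g g^T, whose double contraction with the
diffusion tensor gives the apparent diffusion coefficient along g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "build_b_matrix",
    "b_matrices",
    "read_bval_bvec",
    "write_bval_bvec",
    "fibonacci_directions",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weightings and unit gradient directions.

    Parameters
    ----------
    b_values : (N,) array
        Diffusion weightings in s/mm^2.
    directions : (N, 3) array
        Gradient directions.  Must be unit vectors wherever b > 0; volumes
        with b = 0 may carry a zero vector.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError(f"directions must be (N, 3), got {g.shape}")
        if b.shape[0] != g.shape[0]:
            raise ValueError(
                f"{b.shape[0]} b-values but {g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("negative b-values are not physical")
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(norms - 1.0) > 1e-3))
            raise ValueError(
                "non-unit gradient direction at DW volume index "
                f"{np.flatnonzero(dw)[bad]} (|g| = {norms[bad]:.6f})"
            )
        # store exactly unit-normalized DW directions
        g = g.copy()
        g[dw] /= np.linalg.norm(g[dw], axis=1, keepdims=True)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.shape[0])

    @property
    def dw_mask(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) volumes."""
        return self.b_values > 0

    @property
    def b0_mask(self) -> np.ndarray:
        return ~self.dw_mask

    def validate_for_tensor_fit(self) -> None:
        """Require >= 6 directions spanning symmetric tensors and >= 1 b=0."""
        if not np.any(self.b0_mask):
            raise ValueError("tensor fitting requires at least one b=0 volume")
        n_dw = int(np.sum(self.dw_mask))
        if n_dw < 6:
            raise ValueError(f"tensor fitting requires >= 6 DW volumes, got {n_dw}")
        design = tensor_design_matrix(b_matrices(self))
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError(
                "gradient directions do not span the space of symmetric tensors"
            )


def build_b_matrix(b: float, g: np.ndarray) -> np.ndarray:
    """B matrix of a single Stejskal-Tanner direction: b * g g^T.

    Symmetric, rank one, with trace(B) = b.  For b = 0 the zero matrix is
    returned regardless of g.
    """
    if b < 0:
        raise ValueError(f"negative b-value: {b}")
    g = np.asarray(g, dtype=float)
    if b == 0:
        return np.zeros((3, 3))
    n = np.linalg.norm(g)
    if abs(n - 1.0) > 1e-3:
        raise ValueError(f"gradient direction must be a unit vector, |g| = {n:.6f}")
    g = g / n
    return b * np.outer(g, g)


def b_matrices(scheme: GradientScheme) -> np.ndarray:
    """Stack of (N, 3, 3) B matrices for every volume of a scheme."""
    out = scheme.b_values[:, None, None] * (
        scheme.directions[:, :, None] * scheme.directions[:, None, :]
    )
    return out


# lower-triangular tensor element order used throughout the package
TENSOR_ELEMENT_ORDER = ("xx", "xy", "yy", "xz", "yz", "zz")
_LT_IDX = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


def tensor_design_matrix(bmats: np.ndarray) -> np.ndarray:
    """Design matrix mapping the 6 unique tensor elements to B:D.

    Row i is [Bxx, 2Bxy, Byy, 2Bxz, 2Byz, Bzz] of direction i so that
    design @ d equals the double contraction B_i : D for d in the
    lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
    """
    bmats = np.asarray(bmats, dtype=float)
    cols = []
    for (k, l) in _LT_IDX:
        w = 1.0 if k == l else 2.0
        cols.append(w * bmats[..., k, l])
    return np.stack(cols, axis=-1)


def tensors_to_lower_tri(t: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensors -> (..., 6) lower-triangular vector."""
    return np.stack([t[..., k, l] for (k, l) in _LT_IDX], axis=-1)


def lower_tri_to_tensors(v: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular vector -> (..., 3, 3) symmetric tensors."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    for i, (k, l) in enumerate(_LT_IDX):
        out[..., k, l] = v[..., i]
        out[..., l, k] = v[..., i]
    return out


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read FSL-style bval (one row) and bvec (three rows) text files.

    A transposed bvec file (N x 3 instead of 3 x N) is auto-detected when the
    shape makes the orientation unambiguous.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    if not bval_path.exists():
        raise FileNotFoundError(f"bval file not found: {bval_path}")
    if not bvec_path.exists():
        raise FileNotFoundError(f"bvec file not found: {bvec_path}")
    b = np.atleast_1d(np.loadtxt(bval_path, dtype=float).ravel())
    g = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape[1] == 3:
        pass  # already N x 3 (includes the ambiguous 3 x 3 case, taken as rows)
    elif g.shape[0] == 3:
        g = g.T
    else:
        raise ValueError(f"bvec file {bvec_path} has shape {g.shape}, expected 3xN or Nx3")
    if g.shape[0] != b.shape[0]:
        raise ValueError(
            f"bvec file {bvec_path} has {g.shape[0]} directions but "
            f"bval file {bval_path} has {b.shape[0]} values"
        )
    return GradientScheme(b_values=b, directions=g)


def write_bval_bvec(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform hemisphere direction set via the golden-angle spiral.

    Deterministic stand-in for an electrostatically optimized scheme; adequate
    for simulation and testing (antipodal symmetry of diffusion weighting
    makes a hemisphere sufficient).
    """
    i = np.arange(n) + 0.5
    z = i / n                    # upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
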