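"""Algebra of the linear perturbation model.

The effective diffusion gradient at position r deviates from the nominal one
as G*(r) = (I + Sigma(r)) G, where Sigma is a small, smooth, dimensionless
perturbation matrix lumping eddy-current fields, gradient nonuniformity,
miscalibration, concomitant and cross terms.  To first order only the
symmetric part Sigma+ = (Sigma + Sigma^T)/2 enters the measured signal, via
the perturbation ellipsoid L = I + 2 Sigma+: the perturbed B matrix is
B* ~= B + Sigma+ B + B Sigma+ and the perturbed tensor D* ~= sym(L D).
For isotropic diffusion D = D0 I this collapses to D* = D0 L, which is what
makes a water phantom a direct probe of the field.
"""

from __future__ import annotations

import numpy as np

from .tensor import TensorIndices, tensor_indices

__all__ = [
    "sym_part",
    "ellipsoid_from_sigma",
    "sigma_sym_from_ellipsoid",
    "perturb_gradient",
    "perturb_b_matrix_linear",
    "perturb_b_matrix_exact",
    "perturbed_tensor",
    "ellipsoid_index_maps",
    "assert_positive_definite",
]


def sym_part(sigma: np.ndarray) -> np.ndarray:
    """Symmetric part (Sigma + Sigma^T) / 2; broadcasts over (..., 3, 3)."""
    sigma = np.asarray(sigma, dtype=float)
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def ellipsoid_from_sigma(sigma: np.ndarray) -> np.ndarray:
    """Perturbation ellipsoid L = I + 2 Sigma+ (symmetric by construction)."""
    return np.eye(3) + 2.0 * sym_part(sigma)


def sigma_sym_from_ellipsoid(ell: np.ndarray) -> np.ndarray:
    """Invert the ellipsoid map: Sigma+ = (L - I) / 2.

    An asymmetric input is symmetrized (only the symmetric part is ever
    estimable from data).
    """
    ell = np.asarray(ell, dtype=float)
    asym = np.max(np.abs(ell - np.swapaxes(ell, -1, -2)))
    if asym > 1e-9:
        import warnings

        warnings.warn(
            f"asymmetric ellipsoid input (max asymmetry {asym:.2e}); symmetrizing",
            stacklevel=2,
        )
    return 0.5 * (sym_part(ell) - np.eye(3))


def perturb_gradient(g: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Effective gradient direction g* = (I + Sigma) g.

    Deliberately not re-normalized: the perturbation changes both magnitude
    (effective b-value) and direction.
    """
    g = np.asarray(g, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return g + np.einsum("...ij,...j->...i", sigma, g)


def perturb_b_matrix_linear(bmat: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """First-order perturbed B matrix B + Sigma+ B + B Sigma+.

    This symmetric form is contraction-equivalent to the left product L B:
    for any symmetric D, (B + Sigma+ B + B Sigma+):D = tr(L B D).
    """
    bmat = np.asarray(bmat, dtype=float)
    sp = sym_part(sigma)
    return bmat + sp @ bmat + bmat @ sp


def perturb_b_matrix_exact(b: float, g: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Exact perturbed B matrix b * g* g*^T with g* = (I + Sigma) g.

    Used as the forward model in simulations and as the brute-force oracle
    for the first-order form (their difference is O(||Sigma||^2))."""
    gs = perturb_gradient(g, sigma)
    return b * gs[..., :, None] * gs[..., None, :]


def perturbed_tensor(d: np.ndarray, ell: np.ndarray) -> np.ndarray:
    """Perturbed tensor sym(L D) = (L D + D L) / 2.

    The plain product L D is not generally symmetric; symmetrization leaves
    every measurable contraction B : D* unchanged (trace cyclicity) and keeps
    the result a valid tensor.  For isotropic D = D0 I it reduces to D0 L.
    """
    d = np.asarray(d, dtype=float)
    ell = np.asarray(ell, dtype=float)
    ld = ell @ d
    return 0.5 * (ld + np.swapaxes(ld, -1, -2))


def ellipsoid_index_maps(ell_field: np.ndarray) -> TensorIndices:
    """Voxelwise trace, FA and principal-axis maps of an ellipsoid field.

    In the isotropic-diffusion limit the measured tensor is proportional to
    L, so the trace map of L marks MD-bias regions and its FA map marks
    FA-bias regions of any tensor dataset acquired under the same field.
    """
    return tensor_indices(ell_field)


def assert_positive_definite(ell: np.ndarray) -> np.ndarray:
    """Boolean map of voxels where the ellipsoid is positive definite."""
    ell = np.asarray(ell, dtype=float)
    finite = np.all(np.isfinite(ell), axis=(-2, -1))
    safe = np.where(finite[..., None, None], ell, np.eye(3))
    evals = np.linalg.eigvalsh(safe)
    return finite & (evals[..., 0] > 0)
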