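"""Two-step perturbation-field estimation from phantom data."""

import numpy as np
import pytest

from lpfdti.estimation import (
    LPFModel,
    estimate_dw,
    estimate_lpf_model,
    evaluate_lpf,
    fit_lpf_field,
    grid_world_coords,
    voxelwise_ellipsoid,
)
from lpfdti.lpf import sigma_sym_from_ellipsoid
from lpfdti.shharm import SHCoefficients
from lpfdti.simulation import SimulationConfig, random_lpf, synthesize_phantom
from lpfdti.tensor import DiffusionTensorField


@pytest.fixture
def noiseless_phantom(small_config):
    rng = np.random.default_rng(7)
    sigma, truth = random_lpf(small_config, rng)
    dwi, scheme = synthesize_phantom(sigma, small_config, noise=False)
    return small_config, sigma, truth, dwi, scheme


def test_unperturbed_phantom_fits_isotropic_tensor(small_config):
    cfg = small_config
    sigma = np.zeros(cfg.grid_shape + (3, 3))
    dwi, scheme = synthesize_phantom(sigma, cfg, noise=False)
    raw = voxelwise_ellipsoid(dwi, scheme, cfg.phantom_mask(), cfg.affine)
    d0 = cfg.d_value
    err = np.abs(raw.tensors[raw.mask] - d0 * np.eye(3)).max()
    assert err < 1e-12 * d0


def test_voxelwise_ellipsoid_first_order_accuracy(noiseless_phantom):
    """fitted/D_w = I + 2 Sigma+ up to the quadratic model error."""
    cfg, sigma, _, dwi, scheme = noiseless_phantom
    raw = voxelwise_ellipsoid(dwi, scheme, cfg.phantom_mask(), cfg.affine)
    svox = sigma_sym_from_ellipsoid(raw.tensors[raw.mask] / cfg.d_value)
    err = np.abs(svox - sigma[raw.mask]).max()
    amp = np.abs(sigma[raw.mask]).max()
    assert err < 1.2 * amp**2  # O(||Sigma||^2)


def test_invalid_signals_drop_out_of_mask(small_config):
    cfg = small_config
    sigma = np.zeros(cfg.grid_shape + (3, 3))
    dwi, scheme = synthesize_phantom(sigma, cfg, noise=False)
    bad = tuple(np.array(cfg.grid_shape) // 2)
    dwi[bad][10] = -1.0
    raw = voxelwise_ellipsoid(dwi, scheme, cfg.phantom_mask(), cfg.affine)
    assert not raw.mask[bad]


class TestEstimateDw:
    def _field(self, cfg, tensors):
        return DiffusionTensorField(
            tensors=tensors, affine=cfg.affine, mask=cfg.phantom_mask()
        )

    def test_isotropic_field_returns_d0(self, small_config):
        d0 = 2.1e-3
        t = np.broadcast_to(d0 * np.eye(3), small_config.grid_shape + (3, 3)).copy()
        assert estimate_dw(self._field(small_config, t)) == pytest.approx(d0)

    def test_median_robust_to_corrupted_voxels(self, small_config, rng):
        d0 = 1.6e-3
        t = np.broadcast_to(d0 * np.eye(3), small_config.grid_shape + (3, 3)).copy()
        n = t.shape[0] * t.shape[1] * t.shape[2]
        flat = t.reshape(n, 3, 3)
        corrupt = rng.choice(n, size=n // 10, replace=False)
        flat[corrupt] *= 10.0  # 10% corrupted
        est = estimate_dw(self._field(small_config, flat.reshape(t.shape)))
        assert est == pytest.approx(d0, rel=0.01)

    def test_override_passes_through(self, small_config):
        t = np.zeros(small_config.grid_shape + (3, 3))
        f = self._field(small_config, t)
        assert estimate_dw(f, override=1.234e-3) == 1.234e-3

    def test_empty_roi_raises(self, small_config):
        t = np.ones(small_config.grid_shape + (3, 3))
        f = DiffusionTensorField(
            tensors=t, affine=small_config.affine,
            mask=np.zeros(small_config.grid_shape, bool),
        )
        with pytest.raises(ValueError, match="ROI"):
            estimate_dw(f)


class TestFitLPFField:
    def test_exact_recovery_of_span_member(self, small_config, rng):
        """An ellipsoid generated exactly from an order-3 field is recovered
        to machine precision with unit weights."""
        cfg = small_config
        sigma, truth = random_lpf(cfg, rng)
        d_w = 1.7e-3
        ell = d_w * (np.eye(3) + 2 * sigma)
        fld = DiffusionTensorField(
            tensors=ell, affine=cfg.affine, mask=cfg.phantom_mask(),
            residual_var=np.ones(cfg.grid_shape),
        )
        model = fit_lpf_field(fld, d_w)
        est = evaluate_lpf(model, cfg.grid_shape, cfg.affine)
        np.testing.assert_allclose(est, sigma, atol=1e-10)

    def test_downweighting_beats_uniform_on_corrupted_voxels(self, small_config, rng):
        cfg = small_config
        sigma, _ = random_lpf(cfg, rng)
        d_w = cfg.d_value
        ell = d_w * (np.eye(3) + 2 * sigma)
        mask = cfg.phantom_mask()
        res = np.full(cfg.grid_shape, 1e-12)
        idx = np.argwhere(mask)
        corrupt = idx[rng.choice(len(idx), size=len(idx) // 20, replace=False)]
        for i, j, k in corrupt:  # 5% of voxels: big error, big residual
            ell[i, j, k] += d_w * rng.normal(scale=0.2, size=(3, 3))
            res[i, j, k] = 1e-4
        fld = DiffusionTensorField(
            tensors=ell, affine=cfg.affine, mask=mask, residual_var=res
        )
        est_w = evaluate_lpf(fit_lpf_field(fld, d_w, weights="residual"),
                             cfg.grid_shape, cfg.affine)
        est_u = evaluate_lpf(fit_lpf_field(fld, d_w, weights="uniform"),
                             cfg.grid_shape, cfg.affine)
        err_w = np.abs(est_w - sigma)[mask].mean()
        err_u = np.abs(est_u - sigma)[mask].mean()
        assert err_w < err_u

    def test_single_slice_sampling_raises(self, small_config):
        cfg = small_config
        mask = cfg.phantom_mask()
        plane = np.zeros_like(mask)
        plane[:, :, mask.shape[2] // 2] = True
        fld = DiffusionTensorField(
            tensors=np.broadcast_to(np.eye(3) * 1e-3, cfg.grid_shape + (3, 3)).copy(),
            affine=cfg.affine, mask=mask & plane,
        )
        with pytest.raises(ValueError, match="degenerate|deficient"):
            fit_lpf_field(fld, 1e-3)


class TestEvaluateLPF:
    def test_zero_model_gives_zero_field(self, small_config):
        zero = {k: SHCoefficients(order=3, coefficients=np.zeros(16))
                for k in ("xx", "xy", "yy", "xz", "yz", "zz")}
        model = LPFModel(elements=zero, d_w=1e-3)
        out = evaluate_lpf(model, small_config.grid_shape, small_config.affine)
        assert np.all(out == 0)

    def test_shifted_grid_equals_world_frame_evaluation(self, small_config, rng):
        """The field is fixed in the scanner frame: a 3-cm-offset grid samples
        the same polynomial at shifted world points."""
        cfg = small_config
        _, truth = random_lpf(cfg, rng)
        model = LPFModel(elements=truth, d_w=cfg.d_value)
        affine_b = cfg.affine.copy()
        affine_b[2, 3] += 30.0
        shifted = evaluate_lpf(model, cfg.grid_shape, affine_b)
        coords = grid_world_coords(cfg.grid_shape, cfg.affine) + np.array([0, 0, 30.0])
        oracle = model.sigma_at(coords)
        np.testing.assert_allclose(shifted, oracle, atol=1e-14)


class TestEndToEnd:
    def test_noiseless_recovery_floor(self, noiseless_phantom):
        """Whole pipeline on a noiseless phantom recovers Sigma to the
        quadratic linearization floor."""
        cfg, sigma, _, dwi, scheme = noiseless_phantom
        model = estimate_lpf_model(dwi, scheme, cfg.affine,
                                   mask=cfg.phantom_mask(), d_w=cfg.d_value)
        est = evaluate_lpf(model, cfg.grid_shape, cfg.affine)
        amp = np.abs(sigma[cfg.phantom_mask()]).max()
        err = np.abs(est - sigma)[cfg.phantom_mask()].max()
        assert err < 1e-3 * amp + 1.2 * amp**2

    def test_signal_scale_invariance(self, noiseless_phantom):
        """Multiplying all signals by a constant leaves the model unchanged
        (ADCs are ratio-based)."""
        cfg, sigma, _, dwi, scheme = noiseless_phantom
        m1 = estimate_lpf_model(dwi, scheme, cfg.affine, mask=cfg.phantom_mask(),
                                d_w=cfg.d_value)
        m2 = estimate_lpf_model(dwi * 7.5, scheme, cfg.affine, mask=cfg.phantom_mask(),
                                d_w=cfg.d_value)
        for k in m1.elements:
            np.testing.assert_allclose(
                m1.elements[k].coefficients, m2.elements[k].coefficients, atol=1e-12
            )

    def test_dw_invariance(self, small_config, rng):
        """Doubling the true diffusivity (and regenerating) leaves the
        estimated Sigma unchanged."""
        cfg = small_config
        sigma, _ = random_lpf(cfg, rng)
        out = []
        for d in (cfg.d_value, 2 * cfg.d_value):
            c = SimulationConfig(grid_shape=cfg.grid_shape, d_sim=d)
            dwi, scheme = synthesize_phantom(sigma, c, noise=False)
            m = estimate_lpf_model(dwi, scheme, c.affine, mask=c.phantom_mask(), d_w=d)
            out.append(evaluate_lpf(m, c.grid_shape, c.affine))
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)

    def test_centre_minimal_for_origin_vanishing_field(self, small_config):
        """A gradient-nonuniformity-like field vanishing at the isocentre is
        estimated with minimal amplitude at the phantom centre."""
        cfg = small_config
        coords = grid_world_coords(cfg.grid_shape, cfg.affine)
        sigma = np.zeros(cfg.grid_shape + (3, 3))
        lin = 0.05 * coords[..., 2] / cfg.phantom_radius_mm  # pure l=1, zero at origin
        for i in range(3):
            sigma[..., i, i] = lin
        dwi, scheme = synthesize_phantom(sigma, cfg, noise=False)
        model = estimate_lpf_model(dwi, scheme, cfg.affine, mask=cfg.phantom_mask(),
                                   d_w=cfg.d_value)
        est = evaluate_lpf(model, cfg.grid_shape, cfg.affine)
        amp = np.linalg.norm(est, axis=(-2, -1))
        mask = cfg.phantom_mask()
        r = np.linalg.norm(coords, axis=-1)
        centre = mask & (r < 6.0)
        edge = mask & (r > 0.8 * cfg.phantom_radius_mm)
        assert amp[centre].mean() < 0.5 * amp[edge].mean()


def test_model_json_round_trip_and_frame_check(tmp_path, small_config, rng):
    _, truth = random_lpf(small_config, rng)
    model = LPFModel(elements=truth, d_w=1.6e-3, metadata={"note": "synthetic"})
    model.to_json(tmp_path / "m.json")
    back = LPFModel.from_json(tmp_path / "m.json")
    assert back.d_w == model.d_w
    for k in truth:
        np.testing.assert_allclose(back.elements[k].coefficients,
                                   model.elements[k].coefficients)
    # mismatched frames across elements are rejected
    bad = dict(truth)
    bad["zz"] = SHCoefficients(order=3, coefficients=np.zeros(16), r_ref_mm=999.0)
    with pytest.raises(ValueError, match="frame"):
        LPFModel(elements=bad, d_w=1.6e-3)
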