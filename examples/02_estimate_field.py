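"""Estimate the perturbation field from noisy phantom data.

Runs the realistic measurement chain (Gaussian noise at SNR 50 / 10,
5-mm smoothing) and then the two-step estimator: voxelwise tensor fit of
the phantom, then a 3rd-order solid-harmonic fit of the six matrix
elements.  Compares the recovered field to the ground truth.
"""

import numpy as np

from lpfdti import (
    SimulationConfig,
    delta_epsilon,
    estimate_lpf_model,
    evaluate_lpf,
    gaussian_smooth,
    random_lpf,
    synthesize_phantom,
)

cfg = SimulationConfig(grid_shape=(32, 32, 32))
rng = np.random.default_rng(7)

sigma_true, _ = random_lpf(cfg, rng)
dwi, scheme = synthesize_phantom(sigma_true, cfg, rng, noise=True)
dwi = gaussian_smooth(dwi, cfg.fwhm_mm, cfg.voxel_mm)

model = estimate_lpf_model(dwi, scheme, cfg.affine, d_w=cfg.d_value)
sigma_est = evaluate_lpf(model, cfg.grid_shape, cfg.affine)

mask = cfg.phantom_mask()
de = 100 * delta_epsilon(sigma_true, sigma_est, mask)

print("normalized mean difference per element (%):")
for i in range(3):
    print("   " + "  ".join(f"{de[i, j]:6.2f}" for j in range(3)))
print()
print(f"water diffusivity used     : {model.d_w:.4e} mm^2/s")
print(f"voxels in the harmonic fit : {model.metadata['n_voxels']}")
print("Each entry is mean |true - estimated| over the phantom, normalized by")
print("the mean field magnitude; a few percent means the smooth field is")
print("recovered well despite SNR-10 diffusion-weighted images.")
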