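"""Correct biased phantom tensors and compare the two correction modes.

The measured tensor of an isotropic phantom equals D_w L with
L = I + 2 Sigma+, so its FA is pure bias.  Correcting with only the
diagonal of the estimated matrix removes part of it; the full matrix
(including cross terms) removes most of it — mirroring the observation
that off-diagonal elements matter.
"""

import numpy as np

from lpfdti import (
    SimulationConfig,
    correct_dataset,
    estimate_lpf_model,
    gaussian_smooth,
    random_lpf,
    synthesize_phantom,
    voxelwise_ellipsoid,
)

cfg = SimulationConfig(grid_shape=(32, 32, 32))
rng = np.random.default_rng(11)

sigma, _ = random_lpf(cfg, rng)
dwi, scheme = synthesize_phantom(sigma, cfg, rng, noise=True)
dwi = gaussian_smooth(dwi, cfg.fwhm_mm, cfg.voxel_mm)

model = estimate_lpf_model(dwi, scheme, cfg.affine, d_w=cfg.d_value)
raw = voxelwise_ellipsoid(dwi, scheme, cfg.phantom_mask(), cfg.affine)

fa_meas = raw.indices().fa[raw.mask]
_, idx_diag, _ = correct_dataset(raw, model, mode="diag")
_, idx_full, rep = correct_dataset(raw, model, mode="full")

print(f"mean FA, measured          : {np.nanmean(fa_meas):.4f}")
print(f"mean FA, diagonal corrected: {np.nanmean(idx_diag.fa[raw.mask]):.4f}")
print(f"mean FA, full corrected    : {np.nanmean(idx_full.fa[raw.mask]):.4f}")
print(f"flagged (out-of-regime)    : {rep.n_flagged} of {rep.n_voxels} voxels")
print()
print("Water diffuses isotropically, so every nonzero FA here is artefact;")
print("the full-matrix correction brings the map closest to the truth FA = 0.")
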