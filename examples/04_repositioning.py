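"""Why the field matters for longitudinal studies: repositioning bias.

The perturbation field is fixed in the scanner frame.  Scanning the same
object at two table positions 3 cm apart therefore biases its MD maps
differently, which looks like physiological change.  Correcting both
acquisitions with one phantom-calibrated model removes most of the
apparent difference.
"""

import numpy as np

from lpfdti import LPFModel, SimulationConfig, correct_dataset, evaluate_lpf, random_lpf, synthesize_phantom, voxelwise_ellipsoid

cfg = SimulationConfig(grid_shape=(32, 32, 32))
rng = np.random.default_rng(3)
_, truth = random_lpf(cfg, rng)
model = LPFModel(elements=truth, d_w=cfg.d_value)

mask = cfg.phantom_mask()
md, md_cor = {}, {}
for key, dz in (("pos A", 0.0), ("pos B", 30.0)):
    affine = cfg.affine.copy()
    affine[2, 3] += dz                      # same object, table moved in z
    sigma = evaluate_lpf(model, cfg.grid_shape, affine)
    dwi, scheme = synthesize_phantom(sigma, cfg, noise=False)
    raw = voxelwise_ellipsoid(dwi, scheme, mask, affine)
    md[key] = raw.indices().md[mask]
    _, idx, _ = correct_dataset(raw, model, mode="full")
    md_cor[key] = idx.md[mask]

d_unc = np.abs(md["pos A"] - md["pos B"])
d_cor = np.abs(md_cor["pos A"] - md_cor["pos B"])
print(f"true MD                    : {cfg.d_value:.4e} mm^2/s everywhere")
print(f"mean |dMD|, uncorrected    : {d_unc.mean():.3e} mm^2/s "
      f"({100 * d_unc.mean() / cfg.d_value:.2f}% of MD)")
print(f"mean |dMD|, corrected      : {d_cor.mean():.3e} mm^2/s")
print(f"reduction                  : {d_unc.mean() / d_cor.mean():.1f}x")
print()
print("Identical tissue at two positions shows spurious MD differences that")
print("the scanner-frame correction shrinks several-fold, down to the")
print("quadratic residual of the linear model.")
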