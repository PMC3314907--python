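# Methods

## The model

Diffusion tensor imaging infers a symmetric 3×3 tensor **D** per voxel from
the apparent diffusion coefficient measured along ≥ 6 gradient directions,

    ADC_i = g_i^T D g_i,          ADC_i = ln(S_0 / S_i) / b_i,

where g_i is the unit direction of the i-th diffusion-weighting gradient and
b_i its weighting (the rank-one design matrix B_i = b_i g_i g_i^T carries the
same information; ADCs contract with the unit-trace-normalized B_i / b_i).

Real gradient systems do not produce exactly the requested gradient.  Eddy
currents, coil nonuniformity, amplitude miscalibration, concomitant fields
and cross terms between imaging and diffusion gradients all make the
*effective* gradient deviate from the nominal one.  To first order the
deviation is a spatially smooth, dimensionless matrix field Σ(r):

    g*_i(r) = (I + Σ(r)) g_i.

Only the symmetric part Σ⁺ = (Σ + Σᵀ)/2 enters the measured signal at first
order.  Writing L(r) = I + 2 Σ⁺(r) (the *perturbation ellipsoid*), the
perturbed design and tensor are

    B*_i ≈ B_i + Σ⁺ B_i + B_i Σ⁺        (contraction-equivalent to L B_i),
    D*   ≈ sym(L D) = (L D + D L) / 2.

The left product L D is not symmetric in general; we return the symmetrized
form because the only observable, B : D*, is unchanged by symmetrization
(trace cyclicity) and fitted tensors are symmetric by construction.

Two consequences drive everything in this package:

* **Isotropic limit.**  For D = D₀ I the measured tensor is D₀ L(r).  A
  water phantom (truly isotropic, single diffusivity D_w) therefore measures
  the field directly, and the trace / FA maps of L(r) predict which regions
  of *any* dataset acquired under the same field have biased MD / FA.
* **Correction.**  Given Σ⁺, the measured tensor is inverted voxelwise as
  D = sym(L⁻¹ D*).  "diag" mode uses only the diagonal of Σ (perturbation
  components parallel to the applied gradient); "full" mode uses the whole
  symmetric matrix.  Voxels where L is not positive definite are outside the
  small-perturbation regime and pass through uncorrected, counted in the
  report.  An alternative route (`refit=True`) refits the tensor from
  per-voxel perturbed B matrices; the two agree to first order and the
  difference is a useful cross-validation of the linearization.

## Estimation from phantom data

1. **Voxelwise step.**  Ordinary-least-squares tensor fit of the phantom
   ADCs per voxel (ADC against the mean of all b = 0 volumes).  Under the
   model the fitted tensor is D_w L(r); the per-voxel residual variance of
   the fit is kept as a data-quality proxy.
2. **Spatial step.**  L(r)/1 → Σ⁺(r) = (fitted/D_w − I)/2; each of the six
   unique elements is fitted with a real solid-harmonic expansion of order 3
   (16 coefficients per element) by weighted least squares, weights
   1/(residual variance + 1e-12).  Artefacts that are not proportional to
   the diffusion gradient (vibration, ghosting, flow) do not bias the
   tensor-model fit but inflate its residual, so inverse-residual weighting
   down-weights exactly the voxels they corrupt.

D_w is taken as the median MD in a central sphere (default radius 15 mm)
because measured perturbation fields are smallest near the isocentre and the
median resists corrupted voxels; a temperature-calibrated value can be
supplied instead.  Note the degeneracy: a relative error δ in D_w shifts all
three diagonal Σ⁺ elements by δ/2 while leaving off-diagonal elements
untouched — supplying an accurate D_w matters mainly for the diagonal.

**Basis.**  Regular real solid harmonics r^l Y_lm (harmonic polynomials in
x, y, z), the conventional expansion for gradient-coil fields, evaluated at
arbitrary radius — not surface harmonics on a fixed sphere.  Coordinates are
world mm from the NIfTI affine (origin assumed at the isocentre), divided by
a reference radius (default 150 mm) for conditioning; the fitted span is
independent of that scale.  Ordering is l ascending, m = −l..l; the sphere
normalization of the tesseral basis is internal and recorded in the model
JSON.  Orders > 3 are accepted by the code but untested against any
reference.

## The synthetic phantom

The simulator emulates the validation protocol, and its defaults are the
study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 48³ voxels, 2.3 mm iso | desk-scale analogue of a 96² / 2.3 mm protocol |
| phantom | sphere, 80 % of half-FOV (44 mm) | fills the field of view like a bottle phantom |
| b-value | 1000 s/mm² | protocol value |
| D_sim | ln 5 / b ≈ 1.609e-3 mm²/s | makes the unperturbed DW/non-DW ratio exactly 1/5 |
| directions | 60 + 6 b = 0 | protocol value (golden-angle hemisphere set) |
| field | 6 × 16 solid-harmonic coefficients ~ U[−1, 1] | random 3rd-order fields |
| amplitude | global peak-to-peak 0.1 over the phantom | 10 % of the nominal gradient |
| noise | Gaussian, SNR 50 (b=0), 10 (DW) | SNR defined on the mean in-phantom signal |
| smoothing | 5-mm FWHM Gaussian, ADCs recomputed after | measurement pipeline |

Signals are synthesized with the **exact** forward model
S = S₀ exp(−b |g*|² D_sim) (rank-one perturbed B matrix, not the linearized
one), so simulations exercise the estimator's model error as well as its
noise response.  Noise is Gaussian as specified, not Rician; a `rician`
variant is deliberately out of scope since sub-10 SNR regimes are not
modelled.  Coefficients are drawn in a frame scaled by the phantom radius so
that all orders l = 0..3 contribute comparably over the phantom; the draw is
then rescaled by one global factor so the largest element-wise peak-to-peak
variation equals the configured amplitude (per-element normalization is
available as a flag).  Both of these conventions are choices — the original
normalization of the random draw is not recoverable from published text —
and they affect the *normalized* error metric below, since it divides by the
mean field magnitude.

What the simulator does **not** emulate: EPI readout distortion, motion,
cardiac pulsation, vibration or ghosting artefacts, Rician noise, non-linear
(±-asymmetric) gradient response, and heterogeneous tissue.  A passing
Monte-Carlo here therefore demonstrates the estimator's statistical
behaviour under its own model class, not robustness to every real-world
confound.

## The precision metric

For each trial, per matrix element,

    δε_ij = mean_r |Σ_true,ij − Σ_est,ij| / mean_r (|Σ_true,ij| + |Σ_est,ij|)/2

over the phantom mask, reported in percent and pooled (median) separately
for diagonal and off-diagonal elements.  The denominator convention
("average of the modulus") is ambiguous; `denominator="true_only"` computes
the variant normalized by the true field alone, and the two differ by well
under a percentage point in practice.  At the default conditions the
pipeline lands near 3 % (diagonal) and 2 % (off-diagonal); the noiseless,
unsmoothed floor (pure linearization error) is ≈ 1.9 % / 0.6 % and scales
linearly with the amplitude.  Estimating D_w from the data instead of
supplying it raises the diagonal error to ≈ 20 % through the trace
degeneracy, bracketing historically reported precision figures for this
kind of estimator; which convention a given study used is usually not
printed, so comparisons of the diagonal figure across implementations
should state it.

## Numerical choices and edge cases

* OLS tensor fit (optionally weighted): pseudo-inverse via `lstsq`; a design
  of rank < 6 raises with the reason.  Negative or degenerate eigenvalues
  are preserved, never clipped — corrections operate on the raw tensor.
* Non-positive signals yield NaN ADCs and drop the voxel from masks; whole
  volumes never raise on noise.
* Principal-axis sign: first component (scanning x, y, z) with magnitude
  > 1e-12 made positive.
* Phantom auto-mask: 30 % of the 99th-percentile of the mean b = 0 image,
  eroded 2 voxels — smoothing-contaminated edge voxels violate the smooth
  field assumption.
* FWHM→σ: σ = FWHM / (2√(2 ln 2)), kernel truncated at 4σ, reflect
  boundaries.
* Weighted harmonic fit: rank checked after weighting; deficient columns
  identified from the trailing right singular vectors.
* Degenerate spatial sampling (single slice / line) raises rather than
  extrapolating a 3-D polynomial from a plane.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence([seed, trial])`.

## Known limitations

* The model is first order: residuals after correction are O(‖Σ‖²).  At
  peak-to-peak amplitude 0.1 this leaves a worst-voxel FA of a few 1e-3 in
  a noiseless phantom even when correcting with the *true* field — an
  intrinsic floor of the linear inversion, not an estimation error.
* Only Σ⁺ is estimable from tensor data; the antisymmetric part is neither
  recovered nor needed for tensor correction, but it does affect the exact
  signal of anisotropic tensors at first order, which is invisible in an
  isotropic phantom.
* The field is assumed static between phantom calibration and subject scan
  and tied to the acquisition (slice prescription, timing); a model fitted
  from one protocol should not be applied to another.
* Tractography-level effects of the correction (principal-axis rotation) are
  computed but not validated here.
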