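# Methods

`medfuse` fuses a co-registered CT/MRI slice pair into one image that keeps
the complementary content of both modalities: the high-contrast bone that CT
shows and the soft-tissue texture that MRI shows. This note records the
model, the numerical choices, and what the synthetic test bed does and does
not demonstrate.

## Pipeline model

For sources C and D the pipeline is

1. **Morphological enhancement.** Flat grayscale morphology with a disk
   structuring element b: bottom-hat `Wb = (f • b) − f` collects dark pits
   (noise, shading troughs), top-hat `Ww = f − (f ∘ b)` collects bright
   peaks. The enhanced image is `clip(f + Ww − Wb, 0, 1)`, the standard
   combination that keeps the image content while boosting bright structure
   and suppressing dark artifacts. A literal residue difference
   `clip(Ww − Wb)` is selectable (`preprocess.variant = residue`);
   it discards the image itself and is provided only for comparison. The
   structuring-element radius is the scale separator between "artifact" and
   "anatomy": default 9 px at 256-px images, scaled proportionally with the
   smaller image side (minimum 2), and exposed in the config. Borders are
   reflect-padded so clipped anatomy does not generate spurious residues.
2. **Decolorization.** RGB inputs are mapped to full-range BT.601 YCbCr,
   zero-meaned per channel, and reduced by a 3×3 PCA. The gray image is the
   sum of the three eigenvector projections weighted by `√λk / Σ√λ`,
   rescaled to [0, 1]. The √λ weighting keeps the chroma-borne detail of
   the second and third components in proportion to their contrast, and the
   eigenvector signs are fixed by positive correlation with luminance so
   the output is deterministic (eigenvector sign is otherwise arbitrary).
   Gray inputs pass through unchanged.
3. **Shearlet analysis (LSIST).** An undecimated two-stage transform.
   Multiscale stage: an à-trous non-subsampled pyramid built on the CDF 9/7
   analysis/synthesis low-pass pair (DC gains normalized to 1). With
   analysis response H0 and synthesis response H1 at scale s (frequency
   dilation 2^s), the split is `low = H0·f`, `g = f − H1·low`, which
   satisfies the Bezout identity `H0·H1 + G·1 = 1` and therefore
   reconstructs exactly: `f = H1·low + g`. Directional stage: each high
   band is multiplied in the 2-D DFT domain by Meyer-window wedges defined
   on the pseudo-polar grid (uniform in slope on concentric squares,
   period-4 orientation coordinate) and resampled to the Cartesian DFT
   grid; the squared wedges of each scale sum to one at every frequency, so
   the adjoint recombination is exact. Defaults: 3 scales with (8, 8, 16)
   directions coarse→fine — conventional shearlet settings, config-exposed.
4. **High-band fusion.** A two-branch shared-weight CNN (three 3×3 stride-1
   valid convolutions with 64/128/256 filters, one 2×2 stride-2 max-pool
   after the second, no fully connected layers; a 4×4 convolution forms the
   2-way soft-max head over the 512 concatenated feature maps) scores every
   16×16 block pair with the probability that the C-side block is clearer.
   Run fully convolutionally over a band pair it yields a stride-2 score
   map whose scores are redistributed to pixel resolution by averaging over
   the overlapping 16×16 source blocks (trailing uncovered rows/columns at
   odd sizes are filled by nearest-neighbor replication). The map is
   thresholded at 0.5 (strict), cleaned by an 8×8 majority vote (the even
   window extends one extra row/column toward lower indices; exact 32/32
   ties keep the original pixel), refined by a guided filter with r = 4,
   ε = 0.1 guided by the preprocessed C image (the bands themselves are
   near-zero-mean and supply no edges), and used as convex weights
   `Fh = Dm·Ch + (1 − Dm)·Dh` on the **raw** coefficients. Bands are
   min-max normalized to [0, 1] only for scoring, because the classifier is
   trained on [0, 1] patches while coefficients are signed and unbounded.
   One decision map is computed per (scale, direction) band to preserve
   directional selectivity; `hf.per_band = false` switches to one shared
   map per scale for speed.
5. **Low-band fusion.** Local energy `En = Σ Wc·L²` over a 3×3 all-ones
   template and the match measure `S = 2 Σ Wc·LC·LD / (EnC + EnD)`
   (template included in the numerator so identical bands give S = 1
   exactly; S defined as 1 where both energies vanish). Where S > 0.5 the
   bands are averaged with weight α_max = 0.7 on the higher-energy band and
   α_min = 0.3 on the other; otherwise the higher-energy coefficient is
   selected. The α defaults are a deliberate mild majority: they realize an
   averaging mode distinct from pure selection while still favoring the
   energetic band; the template is unnormalized because normalization
   cancels in S and in every energy comparison. Energy ties go to the
   first input, exactly as the `≥` inequalities are written.
6. **Reconstruction and display.** The fused low band and fused high bands
   are inverted through the adjoint transform (transform-domain linear
   superposition; a literal pixel sum of the two fused images would double
   count content and is not implemented). The reconstruction is then
   affinely mapped to [0, 1] over the window `[min(0, min), max(1, max)]`
   ("anchored" mode): this is the identity whenever the reconstruction
   already lies in [0, 1] and contracts only on overshoot, so fusing an
   image with itself returns the preprocessed image to within transform
   round-off. Strict min-max, clipping, and raw output are config modes.

## Network training

The clarity classifier is trained on synthetic (sharp, Gaussian-blurred)
patch pairs, since clear-versus-degraded discrimination — not any specific
anatomy — is what the score map needs. SGD with batch 128, momentum 0.9,
weight decay 1e-5; learning rate 0.01 and 10 epochs by default (the rate
and epoch count are the package's own choice; only batch size, momentum and
decay are prescribed constants). Training is bit-deterministic under the
seed: fixed He initialization, fixed shuffling streams, float32 throughout.
The engine is pure NumPy: convolutions are evaluated as im2col + GEMM (and
as nine accumulated batched GEMMs in the inference path), so the desk-scale
run — 5000 pairs, 10 epochs — takes a few minutes on one CPU and reaches
held-out accuracy ≥ 0.98 in practice; a 20% split is held out and recorded
in the checkpoint.

## Quality metrics

* `qfab` (edge-information transfer): Sobel strength/orientation
  preservation sigmoids, combined multiplicatively, weighted by source edge
  strength. Constants κ_g = −10, σ_g = 0.5, κ_α = −20, σ_α = 0.75,
  config-exposed. The sigmoids are normalized so that perfect preservation
  scores exactly 1 (the classical unnormalized constants cap slightly
  below 1).
* `crr`: mean of the two Pearson correlations corr(A, F), corr(B, F).
* `avg_gradient`: mean of `sqrt((dx² + dy²)/2)` with forward differences —
  for a unit ramp of width W this equals `1/((W−1)·√2)` exactly.
* `nfab` (fusion artifacts): the fraction of fused edge energy not
  explained by either source, `Σ g_F (1−Q^AF)(1−Q^BF) / Σ g_F`, using the
  same preservation sigmoids. A stricter "masked" variant that counts only
  sites where the fused gradient exceeds both source gradients is
  config-selectable; it is identically zero for any convex pixelwise
  combination (an average can never out-gradient both sources), which makes
  it useless for ranking such baselines — hence the unexplained-energy
  form as default.

Metrics are computed against the preprocessed sources by default, because
those are what the fusion actually consumes; `metrics_on = raw` switches to
the original gray inputs.

## Synthetic data

The phantom generator emulates the structure that makes CT/MRI fusion
nontrivial: a shared elliptical anatomy (skull ring plus interior blobs,
fixed layout, so pairs are exactly co-registered), complementary contrast
(CT: bright ring, flat dark interior; MRI: dark ring, bright interior with
band-limited Gaussian texture), additive Gaussian noise (default sd 0.02),
and a multiplicative first-order illumination ramp with unit mean (default
amplitude 0.3) that the top-hat stage is expected to remove. Patch pairs
are textured crops (near-flat crops rejected) blurred with σ drawn from
[1, 3]; pair order is randomized and labels are exactly balanced by a
seeded permutation.

What passing on phantoms does **not** show: performance on real CT/MRI
anatomy, robustness to registration error (inputs are assumed perfectly
aligned), to modality-specific noise statistics (Rician MRI noise, CT
streaks), or to intensity calibrations other than [0, 1] normalization. The
comparative results against pixelwise averaging are statements about these
study conditions, not about clinical images.

## Problem sizes and tolerances

Default verification sizes: 128×128 images, 3 scales, (8, 8, 16)
directions, 5000 training pairs, 10 epochs, 10 phantom pairs for the
method-versus-average comparison. Transform round trips are exact to
~1e-12 (asserted at 1e-4); wedge partition of unity to ~1e-14 (asserted at
1e-6); morphology and the low-pass fusion rule agree with brute-force
per-pixel oracles to the last bit up to float summation order (asserted at
1e-12); the guided filter agrees with a naive textbook implementation to
1e-6. The 9/7 pyramid is perfect-reconstruction but not Parseval-tight:
the empirical band-energy to image-energy ratio sits near 0.99 and is
asserted to stay within [0.9, 1.3].

## Known limitations

* 2-D single-slice only; no DICOM, volumes, or registration.
* The DFT-domain wedge realization is periodic; symmetric pre-padding
  (`lsist.boundary = symmetric`) is available when wrap-around across
  image borders matters.
* The clarity network is trained on isotropic Gaussian blur; other
  degradations (motion blur, aliasing) are outside its training
  distribution.
* The exact variants of the published metric acronyms differ across the
  literature; the definitions above are the package's declared choices,
  with constants exposed so alternates can be tested.
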