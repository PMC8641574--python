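# Methods

This note records the model implemented by `leafcs`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic-scene experiments do and do not demonstrate.

## The codec

**Signal model.** A hyperspectral cube `X[i, j, k]` holds n-bit unsigned
digital numbers (DN) for rows × cols pixels over `B` bands with strictly
increasing wavelengths. The codec treats values as raw DNs throughout;
normalization to [0, 1] by the full scale `2^n − 1` happens only when
vegetation indices are computed (a stand-in for reflectance calibration,
which is outside scope).

**Band selection (SSDC).** For each interior band `k` and each spatial
block (default 8×8; image-edge remainders merge into the last block), the
band is regressed by ordinary least squares on its two spectral
neighbours, `x(i,j,k) ≈ a + b·x(i,j,k−1) + c·x(i,j,k+1)`, over the block's
pixels. The block's score is the residual standard deviation with the
degrees-of-freedom-corrected divisor (pixel count − 3); the band's SSDC is
the mean over blocks. Strong spectral correlation makes the regression
absorb the signal, leaving the noise — so low SSDC marks a clean band. The
two boundary bands lack a two-sided neighbourhood and are excluded rather
than regressed one-sidedly (simpler, and edge bands are rarely optimal).
An optional flag adds the left spatial neighbour `x(i,j−1,k)` as a third
regressor; the default is spectral-only. On a constant scene with
per-band iid noise of sd σ_k the estimator recovers σ_k to within a few
percent (verified by Monte-Carlo in the test suite); it is exactly
invariant to global offsets and exactly linear in global scale.

**Masking.** k-means (k-means++ init, fixed seed, ≤300 iterations, tol
1e-4) clusters the optimal band's intensities into `m` classes, renumbered
by ascending cluster mean. The class with the most pixels is taken as
background (leaves occupy a minority of the frame; overridable), and the
remaining classes form the primary binary mask. 8-connected components
smaller than `min_area` (default 16 px — k-means on a noisy band produces
speckle; 0 disables) are removed; survivors are labeled 1..n in row-major
first-occurrence order. Labeling is idempotent on its own support, and
per-ROI areas satisfy `Area_ROIs = Σ Area_ROI(i)`.

A caveat found during development and kept visible here: on a scene with
one tight background mode and several similar leaf modes, the sum-of-squares
objective can prefer *splitting the large background cluster* over
separating two similar leaves once `m` exceeds the number of true
intensity levels. On the two-level synthetic scenes `m = 2` segments
perfectly; larger `m` (the 3–4 typical of real bench scenes with shadows
and stage structure) is exposed as a parameter. Holes inside leaves are
not filled — no morphology is applied.

**Blocking and expansion.** Each ROI is tiled by 2×2 blocks on the even
grid anchored at the ROI's bounding-box origin; grid cells containing at
least one ROI pixel are kept, so every ROI pixel is coded exactly once.
A block's four pixels are emitted in the fixed zigzag order
(0,0),(0,1),(1,0),(1,1) for band 1, then band 2, …, giving one vector of
length `N = 4·B`. Non-ROI (or out-of-frame) slots in boundary blocks are
filled with the mean of the block's valid pixels in that band before
measurement — this avoids step artifacts at leaf edges — and are never
written back on reconstruction; a zero-fill rule is available. Inverse
expansion rounds to the nearest integer and clips to `[0, 2^n − 1]`, and
is the exact identity on valid pixels for integer inputs.

**Measurement.** `Y = Φ·X` with Φ an M×N matrix of iid N(0, 1/M) entries
drawn from a seeded generator; `M = ⌈R·N⌉` (at least 1, and clamped to
N−1 so at least one degree of compression remains when the capped rate
approaches 1). One matrix is shared by all blocks of a ROI and only its
seed travels in the header — storing Φ itself would defeat compression.
The per-ROI seed is `seed XOR roi_id`, masked to 31 bits.

**Sparse basis and recovery.** The basis is the orthonormal DCT-II matrix
(row 0 constant `1/√N`; row r, column c equal to
`√(2/N)·cos((2c+1)rπ/2N)`), orthonormal to better than 1e-9 up to
N = 4096. Expansion vectors of natural scenes are smooth band-to-band, so
they are sparse in their *forward* DCT coefficients: the synthesis
operator used in the sensing composition is the transpose (inverse DCT),
`x = Ψᵀ s`, `A = Φ·Ψᵀ`. StOMP recovers `s` in stages: correlate the
residual against the column-normalized A, admit every atom with
`|c_j| > t·σ` where `σ = ‖r‖₂/√M` (defaults t = 2.5, ≤10 stages, relative
residual tolerance 1e-6), refit the support by least squares, repeat.
A selection batch that would push the support past M atoms is truncated
to its strongest members, and coefficients left numerically zero by the
final refit are pruned.

Two recovery properties worth knowing:

- The threshold is *conservative by design*: an atom qualifies only if its
  correlation exceeds `t/√M` of the residual norm, so for M below about
  `t² ≈ 6` measurements nothing can ever qualify and the recovery is the
  zero vector. This is the honest behaviour of the staged rule at extreme
  undersampling, and it is what the whole-frame baselines hit at a 5%
  rate on 32-band scenes.
- At the theoretical lower edge M = 4k for k-sparse signals, success rates
  are ~65% (N = 128, k ∈ {4, 8}, 20 seeds): the threshold exceeds the
  per-atom share of equal-energy supports. From M ≈ 5–6k upward, noiseless
  recovery exceeds 95%; the test suite exercises M = 6k.

**Rate allocation.** With a whole-image target rate `p` and the primary
mask, every ROI is coded at `Ratio_p = (Area_image / Area_ROIs)·p`, capped
at 0.99 with a warning — the budget the discarded background frees up.
(The alternative literal reading, in which the numerator is the ROI area
itself and `Ratio_p ≡ p`, is selectable by the `literal_area_whole` flag;
it contradicts the reallocation premise and is off by default.) With
per-ROI rates the realized whole rate is the area-weighted mean
`Σ Area_ROI(i)·p(i) / Area_ROIs`, which the stored measurement counts
match to within the ⌈·⌉ rounding bound of 1/N per ROI.

**Baselines.** BCS applies the identical block/expand/measure/StOMP
machinery to every 2×2 block of the full frame (one shared Φ, uniform
rate; odd-dimension remainders are partial blocks with mean fill). SSCS
compresses each pixel's spectral vector (length B) independently with a
shared Φ and a B-sized DCT basis. The paper-trail for both is thin in the
literature this package follows, so they are implemented as the closest
ablations of the ROI codec — no mask, and no spatial blocking,
respectively — and reports should treat them as such.

## Synthetic scenes

`SceneParams` defaults define the study conditions: 64×64 px, 32 bands
over 450–950 nm, three non-overlapping elliptical leaves (random centers,
axes 13–19% of the frame side, random rotation, optional sinusoidal
boundary perturbation for non-convexity), a flat background at 2% of full
scale, 16-bit quantization, and iid Gaussian sensor noise of sd 40 DN
(~0.06% of full scale — mild, as for a cooled line-scan camera; the
leaf/background contrast is two orders of magnitude larger). Leaf spectra
follow a logistic red edge from a visible trough (0.08 reflectance,
±15% per-leaf jitter) to a NIR plateau (0.55, ±8%), red-edge center
715 ± 5 nm, width 12 nm, plus a Gaussian green bump at 550 nm — enough
structure to make R550/R670/R700/R720/R750 and hence TVI and DD
meaningful. One seed drives geometry, spectral jitter and noise. A
per-band noise-sd vector can replace the scalar to exercise band
selection.

What the generator does *not* emulate: radiative-transfer leaf optics
(no PROSPECT), specular highlights, venation and within-leaf gradients,
stage texture, or spectrally structured sensor noise. Passing tests
therefore demonstrate the codec's internal correctness and its behaviour
on compressible vegetation-like signals, not performance on any particular
instrument's data.

## The synthetic study

The acceptance script and the end-to-end tests run the full pipeline on
three scene seeds and measure, at whole rates 5/10/20%:

- ROI-restricted PSNR of the ROI codec (background budget reallocated:
  at 5% whole rate and ~15% leaf coverage the effective ROI rate is
  ~30%, M ≈ 40 of N = 128), versus BCS and SSCS at the same whole rate.
  The orderings `ROI codec ≥ BCS ≥ SSCS` and PSNR non-decreasing in rate
  hold on every seed tried, by wide margins for the first inequality
  (~20 dB) and narrow ones for the second — at a 5% rate both baselines
  sit in the sub-threshold regime described above (BCS: M = 7, SSCS:
  M = 2) and recover at most their near-constant blocks' DC components.
- TVI and DD RMSE per pixel (the stricter convention; a mean-spectrum
  mode is available and coincides under homogeneity).
- Near-exact reconstruction (>80 dB, typically ~105 dB) of a scene whose
  block vectors are exactly 8-sparse in the basis, coded at M = 64 —
  the end-to-end noiseless sanity check.

Problem sizes (64×64×32 scenes, three seeds, N = 128 blocks) were chosen
so the whole study runs in seconds on one core while leaving every
operating regime of the codec — sub-threshold, transitional, and
comfortable — represented.

## Numerical conventions and edge cases

- MSE averages squared error over (ROI pixels × all bands); a uniform
  error d gives MSE = d² regardless of ROI size or band count. Identical
  inputs report PSNR = +inf (a sentinel, not a number in reports).
- PSNR uses the declared bit depth, not the storage word: 12-bit data in
  16-bit words peaks at 4095.
- Nearest-wavelength lookup breaks ties toward the lower wavelength; a
  vegetation-index anchor farther than 10 nm from every band is an error.
- k-means classes are renumbered by ascending mean so class indices are
  deterministic; `m = 1` returns an all-zero map; `m` exceeding the
  number of distinct intensities is an error.
- Blocks with fewer than 8 pixels never arise in SSDC scoring because
  remainders merge into the last block and block dims are ≥ 4.
- Least-squares rank deficiency inside StOMP is handled by `lstsq`'s
  minimum-norm solution; duplicate-direction atoms therefore cannot
  crash a stage.
- The `.hcs` container validates payload lengths against the header on
  read and names the offending ROI; the mask is stored run-length encoded
  and reproduces exactly.

## Known limitations

- SSCS and BCS are interpretations (ablations), not reimplementations of
  any specific published variant.
- The background is reconstructed as a constant fill (default 0); the
  codec is lossy-by-omission outside the mask by design.
- No entropy coding of measurements and no rate-distortion optimization;
  the stored size is `Σ blocks_i · M_i` float32 values plus the header.
- Mask quality at `m > 2` on low-contrast scenes inherits k-means'
  preference for splitting large clusters (see above); no morphological
  cleanup is applied.
- 12-bit cubes are stored in 16-bit words (no bit packing).
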