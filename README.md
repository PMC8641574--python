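# leafcs

ROI-aware compressive sensing for plant-leaf hyperspectral cubes.

Hyperspectral images (HSIs) of plant leaves are huge — hundreds of narrow
bands over a megapixel frame — yet the information of interest lives only
in the leaves, which typically occupy a minority of the frame. `leafcs`
implements a codec that discards the background entirely and spends the
whole measurement budget on the leaf regions:

1. **Band selection.** Every band is scored with the spatial/spectral
   decorrelation criterion (SSDC): regress band *k* on its spectral
   neighbours *k−1, k+1* within small spatial blocks and average the
   residual standard deviation. The minimum-SSDC band is the cleanest and
   is used for segmentation.
2. **Masking.** k-means on the optimal band separates leaf from
   background; 8-connected components of the resulting binary mask are
   labeled 1..n in left-to-right, top-to-bottom order, giving one
   arbitrary-shape region of interest (ROI) per leaf.
3. **Coding.** Each ROI is tiled with 2×2 spatial blocks; a block's pixels
   across all bands are expanded zigzag, band by band, into one vector of
   length N = 4·bands; the vector is measured as Y = ΦX with a seeded
   random Gaussian matrix Φ ∈ R^(M×N), M = ⌈R·N⌉ for sampling rate
   R = M/N. Only Y, the mask, the per-ROI rates and the matrix seeds are
   stored.
4. **Recovery.** Each block is recovered by staged orthogonal matching
   pursuit (StOMP) against the sensing matrix A = ΦΨ, where Ψ is the
   orthonormal DCT basis, then inverse-expanded into the output cube
   (background set to 0).

Because the background's budget is reallocated, a whole-image target rate
*p* buys every ROI an effective rate
`Ratio_p = (Area_image / Area_ROIs) · p`; ROIs can also carry individual
rates p(i), with realized whole rate
`Ratio_whole = Σ Area_ROI(i)·p(i) / Area_ROIs`. Reconstructions are
evaluated spatially (per-ROI MSE/PSNR with
`PSNR = 10·log10((2^n − 1)² / MSE)` for n-bit samples) and spectrally
(RMSE of the red-edge vegetation indices
`TVI = 0.5·[120·(R750 − R550) − 200·(R670 − R550)]` and
`DD = (R750 − R720) − (R700 − R670)`).

Two reference codecs built from the identical machinery serve as
baselines: **BCS** (blocking compressive sensing: the same 2×2-block codec
applied to every block of the full frame, background included) and
**SSCS** (single spectral compressive sensing: each pixel's spectral
vector compressed independently, no spatial blocking).

Since real leaf cubes are bulky, the package ships a synthetic-scene
generator (`leafcs.synthetic_leaf`) that produces elliptical "leaves" with
vegetation-like reflectance spectra — green bump, chlorophyll absorption
trough near 670 nm, logistic red edge, NIR plateau — on a flat dark
background, quantized to 12 or 16 bits with Gaussian sensor noise, plus
the ground-truth labeled mask.

## Worked example

```python
import leafcs as lc

# generate a synthetic three-leaf scene (64 x 64 px, 32 bands, 16-bit)
cube, truth = lc.generate_leaf_scene(lc.SceneParams(rng_seed=1))

# 1. pick the cleanest band and extract the labeled leaf mask
band = lc.select_optimal_band(lc.compute_ssdc_curve(cube))
classes = lc.cluster_band(cube.data[:, :, band], m=2, seed=0)
labels = lc.label_rois(lc.extract_primary_mask(classes))
areas = lc.roi_areas(labels)
print(f"optimal band: {band} ({cube.wavelengths[band]:.0f} nm), "
      f"{len(areas.per_roi)} ROIs covering {areas.total}/{areas.image} px")

# 2. compress at a 5% whole-image rate, background discarded
scene = lc.hcsmaroi_compress(cube, labels, lc.RatePlan(p=0.05), seed=7)
roi1 = scene.rois[1]
print(f"per-ROI rate {roi1.rate:.3f} (M={roi1.m} of N={roi1.n}), "
      f"{scene.n_measurements} stored measurements")

# 3. reconstruct and evaluate
recon = lc.hcsmaroi_reconstruct(scene)
for rid in sorted(areas.per_roi):
    mse, psnr = lc.psnr_roi(cube, recon, labels, rid)
    tvi = lc.index_rmse(cube, recon, labels, "TVI", rid)
    print(f"ROI {rid}: PSNR {psnr:.2f} dB, TVI RMSE {tvi:.3f}")
```

prints

```
optimal band: 15 (692 nm), 3 ROIs covering 745/4096 px
per-ROI rate 0.275 (M=36 of N=128), 7488 stored measurements
ROI 1: PSNR 28.05 dB, TVI RMSE 8.045
ROI 2: PSNR 29.24 dB, TVI RMSE 5.196
ROI 3: PSNR 28.85 dB, TVI RMSE 5.963
```

The leaves cover 18% of the frame, so the 5% whole-image budget buys each
ROI an effective 27.5% sampling rate — which is why the ROI codec beats
whole-frame coding by a wide margin at low rates. A PSNR near 28 dB at a
5% rate means the reconstructed leaf radiance is within roughly 2–3% of
full scale per sample; the TVI values themselves span ~0–40 on these
scenes.

The same flow is available from a shell:

```sh
leafcs synth --rows 64 --cols 64 --bands 32 --leaves 3 --seed 1 --out scene.hdr
leafcs band --in scene.hdr
leafcs mask --in scene.hdr --m 2 --out mask.csv
leafcs compress --in scene.hdr --mask mask.csv --rate 0.05 --seed 7 --out scene.hcs
leafcs reconstruct --in scene.hcs --out recon.hdr
leafcs evaluate --orig scene.hdr --recon recon.hdr --mask mask.csv --report report.json
```

Cubes are read and written as ENVI header/raster pairs (BSQ written;
BSQ/BIL/BIP read; unsigned-integer samples, 12-bit data stored in 16-bit
words with a `bit depth` header key). The compressed container (`.hcs`) is
a JSON text header — dimensions, wavelengths, run-length-encoded mask,
per-ROI rates/M/seeds — followed by raw little-endian float32 measurement
vectors, so its size is directly auditable.

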