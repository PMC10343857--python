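# ir2dcos

Species identification from infrared fingerprints via two-dimensional
correlation spectroscopy (2D-COS) images and a residual CNN.

Closely related plant species — e.g. medicinal herbs whose powders must be
authenticated before clinical use — often share nearly identical FT-IR peak
positions and differ only in relative peak intensities, which makes 1-D
spectra hard to discriminate directly. This toolkit implements a full
pipeline that turns each 1-D absorbance spectrum into two-dimensional
correlation maps, renders them as images, and classifies the images with a
small residual CNN:

1. **Spectra handling** — wide-table text I/O, min-max or vector
   normalization, per-class averaging, and extraction of characteristic
   feature bands (3500–3000, 3000–2750, 1750–1100, 1100–400 cm⁻¹, plus the
   full 4010–365 cm⁻¹ window).
2. **2D-COS** — a sinusoidal perturbation expands a static spectrum into an
   *n*-step series; subtracting the per-wavenumber mean gives the dynamic
   spectra ỹ(ν, tᵢ). The synchronous map is
   Φ(ν₁,ν₂) = (n−1)⁻¹ Σᵢ ỹ(ν₁,tᵢ) ỹ(ν₂,tᵢ); the asynchronous map is
   Ψ(ν₁,ν₂) = (n−1)⁻¹ ỹ(ν₁)ᵀ N ỹ(ν₂) with the Hilbert–Noda matrix
   N_jk = 0 (j = k), 1/(π(k−j)) (j ≠ k); the integrative map is the
   elementwise product I = Φ·Ψ.
3. **Imaging** — maps are rendered as axis-free RGB heatmaps with
   zero-centred diverging colours (scale-invariant symmetric normalization).
4. **Splitting** — a stratified random 10 % external-validation holdout,
   then the Kennard–Stone max-min algorithm picks the training set (70 % of
   the total) from the remainder; the rest (20 %) is the test set.
5. **Classification** — a residual CNN (stem conv + BatchNorm + ReLU, four
   stages of one convolution block plus identity blocks — 4 + 6 blocks in
   total — global average pooling, softmax head) trained with SGD
   (lr 0.01, momentum 0.9, weight decay 1e-4, cross-entropy, 40 epochs),
   implemented in pure NumPy.

Because curated spectral libraries of closely related species are rarely
public, the package ships a first-class synthetic-data generator: classes
share ten characteristic peak positions (3292, 2922, 2849, 1732, 1610,
1510, 1422, 1371, 1030, 920 cm⁻¹) and differ by reproducible per-peak
amplitude multipliers, with per-sample amplitude jitter, baseline drift and
additive noise.

## Worked example

```python
from ir2dcos import generate_dataset, RunConfig, run_pipeline

spectra = generate_dataset(n_classes=7, n_per_class=25, seed=1)
manifest = run_pipeline(RunConfig(seed=1, map_type="sync"), spectra)
r = manifest["train_report"]
print(f"test acc {r['final_test_accuracy']:.3f}  "
      f"external acc {r['external_accuracy']:.3f}  "
      f"loss {r['test_loss'][-1]:.4f}")
```

prints (40 epochs of CPU training, ~1 min):

```
test acc 1.000  external acc 1.000  loss 0.0048
```

i.e. all 36 Kennard–Stone test spectra and all 14 held-out external spectra
are assigned to the correct one of the 7 synthetic classes, with a final
test cross-entropy of 0.0048. The same run from the shell:

```bash
ir2dcos simulate --classes 7 --per-class 25 --seed 1 --out spectra.csv
ir2dcos train spectra.csv --seed 1 --out runs/demo
ir2dcos grid spectra.csv --bands bandA,bandB,bandC,bandD,fused,full --out grid.csv
```

`sklearn`-style estimators (`TwoDCosTransformer`, `MapImageRenderer`,
`ResidualCNNClassifier`) expose each stage for use in your own pipelines.

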