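# Methods

## The model

The pipeline assumes the discriminating information between closely
related species lies in the *relative intensities* of shared absorption
bands, not in peak positions. 2D correlation spectroscopy spreads a
perturbation-induced series of spectra over two wavenumber axes:

- dynamic spectra: ỹ(ν, tᵢ) = y(ν, tᵢ) − ȳ(ν), with ȳ the mean over the
  n perturbation steps, so every column of the series is mean-centred;
- synchronous map Φ(ν₁,ν₂) = (n−1)⁻¹ Σᵢ ỹ(ν₁,tᵢ) ỹ(ν₂,tᵢ) — in matrix
  form (n−1)⁻¹ ỸᵀỸ, hence symmetric, non-negative on the diagonal and
  positive semidefinite by construction;
- asynchronous map Ψ(ν₁,ν₂) = (n−1)⁻¹ ỹ(ν₁)ᵀ N ỹ(ν₂), where N is the
  discrete Hilbert–Noda matrix N_jk = 0 (j = k), 1/(π(k−j)) (j ≠ k),
  implemented exactly from this formula (not via FFT Hilbert
  transforms); N is antisymmetric, so Ψ is antisymmetric with a zero
  diagonal;
- integrative map I = Φ·Ψ elementwise (antisymmetric).

### Synthetic perturbation

Routine FT-IR fingerprinting measures one static spectrum per sample, so
the perturbation series is generated: step i at grid point ν is
s(ν)·(1 + a·sin(2π·c·i/n + g·(ν − ν₀))). Defaults n = 16 steps,
modulation depth a = 0.05, c = 1 cycle, phase gradient g = 0. The
modulation is multiplicative so dynamic amplitude stays proportional to
local absorbance and strong bands dominate the auto-peaks; an additive
mode is available by flag.

With g = 0 every wavenumber is modulated in phase and Ψ is identically
zero. The pipeline therefore runs with g = 0.005 rad·cm (about π of
phase spread across the 1750–1100 cm⁻¹ band) whenever asynchronous or
integrative maps are wanted; this value is fixed in `RunConfig` and
logged in every manifest.

### A note on the discrete Hilbert–Noda kernel

For two pure sinusoids with phase offset Δφ sampled over whole cycles,
the synchronous cross-peak equals ½A₁A₂cos(Δφ) (up to the n/(n−1)
sampling factor) essentially exactly, and the asynchronous cross-peak is
*proportional* to ½A₁A₂sin(Δφ) to machine precision. The
proportionality constant — the kernel's gain — is below 1 (≈ 0.87 at
n = 64 for the fundamental) and converges only slowly with n, because
the truncated 1/(k−j) kernel is not the exact periodic Hilbert
transformer. The phase *law* (cos/sin dependence) is what the tests
assert; absolute asynchronous magnitudes inherit the kernel gain.

## Synthetic data generator

Each class recipe places Gaussian peaks (Lorentzian available) at the
ten characteristic wavenumbers 3292, 2922, 2849, 1732, 1610, 1510,
1422, 1371, 1030, 920 cm⁻¹ with fixed half-widths (16–120 cm⁻¹,
broadest for the O-H stretch) and base amplitudes 0.2–0.6 a.u. Classes
differ by per-peak lognormal amplitude multipliers with log-sd
`class_spread` = 0.35 (the separability dial); each sample additionally
receives lognormal amplitude jitter (log-sd 0.08), a class-specific
linear baseline tilt (~N(0, 2·10⁻⁶) a.u./cm⁻¹) and i.i.d. Gaussian
noise (sd 0.002 a.u.). These values were chosen once as plausible for
dried-powder FT-IR at 4 cm⁻¹ resolution: peak-height class differences
of tens of percent, within-class variation an order of magnitude
smaller, and instrument noise two orders below the signal.

The default grid descends 4010 → 365 cm⁻¹ in 4 cm⁻¹ steps (912 points;
endpoints inclusive where they fall on the step lattice, final partial
step dropped).

What the generator does *not* emulate: correlated chemical composition
across peaks, non-linear baselines (scatter, water vapour), peak-shape
changes, wavenumber calibration drift, or instrument-to-instrument
variance. Passing tests therefore demonstrate that the pipeline
recovers amplitude-pattern class structure under realistic noise — not
that any particular real-world taxon is separable.

## Splitting

External validation holds out round(0.1·class size) samples per class
(stratified, seeded, at least 1 when the class has ≥ 2 samples;
singleton classes stay in the model set with a warning). Kennard–Stone
then runs globally on the normalized 1-D spectra of the model set
(Euclidean distances, per-class mode available): the first two picks
are the most distant pair, each later pick maximizes its minimal
distance to the chosen set, ties broken toward the lowest index. The
training size is floor(7/9 · model size), i.e. 70 % of the total under
the 70/20/10 ratios. Kennard–Stone itself is deterministic; only the
holdout consumes the seed.

## Rendering

Maps are resampled bilinearly to size² pixels (default 224 for the
classifier's canonical input; the synthetic study uses 32) and mapped
through a diverging palette ("coolwarm") with symmetric scaling:
[−max|m|, +max|m|] → [0, 1], so zero sits at the palette midpoint and
rendering is invariant to the map's overall scale. No axes or text are
drawn. Bilinear resampling commutes with transposition, so symmetric
synchronous maps render to transpose-symmetric images. A
percentile-scaling and filled-contour mode exist but are not defaults.

## Classifier

Architecture: stem convolution (7×7 stride 2 at 224 px; the study uses
3×3 stride 1 at 32 px) → BatchNorm → ReLU → four stages, each one
projection ("convolution") residual block followed by identity blocks
— plan (1, 2, 2, 1), i.e. 4 convolution + 6 identity blocks — → global
average pooling → fully connected softmax head. Channel widths default
(16, 32, 64, 128); the study uses (8, 16, 32, 64). Every residual
block computes ReLU(F(x) + shortcut(x)); identity blocks preserve
shape exactly, and zeroing F's final BatchNorm scale/shift reduces
them to the identity on non-negative inputs.

Training: SGD with momentum 0.9, learning rate 0.01, weight decay
1e-4, cross-entropy loss, 40 epochs, batch size 16. Spatial sizes of
every convolution obey n_out = ⌊(n_in + 2p − f)/s⌋ + 1 and are audited
programmatically. After each epoch the BatchNorm running statistics are
recalibrated with a cumulative-average pass over the training images
(as in stochastic weight averaging's BN update): with ~8 minibatches
per epoch the exponential running estimates otherwise lag the batch
statistics used during optimization, and evaluation-mode accuracy
oscillates spuriously.

Augmentation: the classifier exposes random resized crop (scale
0.9–1.0) and transpose flip (valid for symmetric synchronous maps
only); both are opt-out. The pipeline's run configuration disables
augmentation by default: at the study scale (125 training images,
rendering already scale-normalized) crop jitter removed real
amplitude-pattern signal and measurably hurt test/external accuracy.

Determinism: all randomness (weight init, batch shuffling,
augmentation, holdout) flows from explicit integer seeds; reruns on
one device are bit-identical, which the manifest's per-stage content
hashes make checkable. Cross-hardware bit-reproducibility is not
promised (BLAS kernel differences).

## The synthetic study

The end-to-end experiment mirrors a small authentication campaign:
7 classes × 25 samples, min-max normalization, 70/20/10 split
(14 external, 125 train, 36 test), the 1750–1100 cm⁻¹ band
(163 grid points), per-sample 2D-COS maps rendered at 32 px, 40
epochs. Problem sizes were chosen so the whole study runs in about a
minute per map type on one CPU core. Synchronous maps reach perfect
test and external accuracy at the default class spread; asynchronous
maps (with the nonzero phase gradient) perform comparably on this
synthetic data — the synthetic classes encode their identity purely in
amplitude patterns, which both map types inherit, so the study checks
the ordering sync ≥ async rather than a strict gap.

## Known limitations

- The NumPy engine targets small models and images; it is single-core
  GEMM-bound and has no GPU path.
- Per-sample maps from a deterministic synthetic perturbation are
  rank-limited (the modulation adds at most a few independent
  components per sample), so map structure is highly redundant with
  the 1-D spectrum; with a real physical perturbation series the same
  code paths apply unchanged via `make_dynamic` on measured series.
- The fused-band variant concatenates band extractions before 2D-COS;
  averaging per-band maps is a reasonable alternative not implemented
  as a default.
- Whether normalization should precede averaging is ambiguous in
  routine practice; the default is normalize-then-average, recorded in
  run metadata.
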