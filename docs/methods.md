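# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the order the pipeline runs.

## Conventions

All rasters are row-major with origin top-left; every crop or box is
half-open `[r0, r1) × [c0, c1)` in pixel coordinates. Intensity planes
carry a nominal bit depth (8/12/16); 12-bit confocal data lives unscaled in
16-bit containers on disk, with the nominal depth declared at read time.
Multi-page TIFFs are z-stacks in acquisition order (−5, −2.5, 0, +2.5,
+5 µm). Label masks are single-channel rasters with a JSON sidecar legend
(`0 background, 1 Healthy, 2 GP3, 3 GP4, 4 Cribriform, 5 Glomeruloid,
6 GP5`); no palette inference is ever attempted.

## Virtual staining

**D&E → H&E.** Per-pixel Beer–Lambert recoloring: each channel is
normalized by its plane maximum, gamma-compressed (defaults
γ_DRAQ5 = γ_Eosin = 1.5; the contract requires γ > 1, which darkens
mid-tones and gives nuclei more visual weight than a linear map), and
multiplied into RGB optical-density vectors. Defaults are the conventional
hematoxylin (0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11) directions,
scaled to unit maximum absorbance; both are configurable. An all-zero
channel contributes no absorbance (division guard), so a zero D&E pair
renders uniform white. The map is pixel-separable and monotone
non-increasing in each channel, which the tests exploit as invariants.

**H&E → D&E.** Grayscale conversion uses standard luma weights
(0.299, 0.587, 0.114). The nuclei mask takes pixels strictly below the
lower of two multi-Otsu thresholds (255 bins), then erodes with a
radius-1 disk; structuring elements default to the smallest symmetric
disk since nothing larger is warranted. Inversion is defined as
(255 − v)/255 applied to nonzero pixels only, so masked-out zeros stay
zero. Noise is i.i.d. Gaussian per pixel on the [0, 1] scale with variance
10⁻⁴. The channel chain is mask → invert → noise → grayscale dilation
(disk 1) → Gaussian smooth (σ = 0.5) → × 4095 → z-normalize.
Z-normalization is per plane (per crop downstream), matching the per-crop
normalization used everywhere else. With noise off, DRAQ5 support is
contained in the nuclei mask dilated by the morphological radius plus the
smoothing kernel's finite footprint — the containment tests account for
that extra reach explicitly.

**Multi-Otsu.** Implemented as an exact dynamic program over the binned
histogram maximizing Σ S²/W (equivalent to between-class variance),
O(k·B²); ties resolve toward the smallest cut indices. Thresholds are
reported on the input intensity scale (left edge of the upper class's
first bin), so "strictly below threshold" selects the lower class.
Constant images raise a degenerate-input error; callers that can proceed
(masking functions) catch it and return an empty mask with a warning.

## Preprocessing

**Rolling-ball background subtraction** is grayscale opening with a
sliding paraboloid z(d) = d²/(2r), the curvature a ball of radius r
(default 50 px) has at its apex. The paraboloid separates over axes
(d² = dx² + dy²), so each erosion/dilation runs as two 1-D passes whose
support is truncated where the paraboloid's depth exceeds the image's
dynamic range. Fluorescence is dark-background, so no inversion is
applied. The tests verify equality (within one grey level) against a
brute-force 2-D opening with an explicitly rasterized paraboloid.

**CLAHE** uses clip limit 0.01 on an 8 × 8 tile grid (library defaults,
exposed in config); output is float [0, 1]; constant input maps to
constant output rather than amplifying nothing.

**Crop grid.** The physical crop edge is 245.52 µm; the pixel edge is
round-half-away-from-zero of edge/pitch (356 px at 0.69 µm, 471 px at the
instrument's unrounded ~0.5213 µm, 472 px at exactly 0.52 µm — the printed
471 arises from pitch rounding, and the formula is authoritative here).
The grid anchors at (0, 0) and discards partial right/bottom tiles rather
than padding: crops dominated by background are dropped later anyway, and
padding would fabricate tissue.

**Stain normalization** is luminosity standardization (95th-percentile
luminance mapped to white; the percentile is this package's choice) plus a
two-stain non-negative factorization of optical density, OD ≈ C·S, with
multiplicative updates warm-started at the conventional H&E directions so
the factors converge to the image's actual stain basis instead of an
arbitrary non-negative rotation. The source stain matrix is replaced by
the target's, per-stain concentrations rescaled to the target's 99th
percentiles, and the result re-exponentiated. This is a deliberate,
contract-compatible stand-in for sparse-dictionary stain separation; its
recovery accuracy (cosine ≥ 0.95 per stain on synthesized images) is
tested directly.

## Ground truth and tasks

Annotations are gated by the epithelial mask (outside → background);
gating is idempotent. Crop labels use the modal non-background class with
two removal rules: predominant count < 15 % of all crop pixels ("pixels
of the whole crop", implemented literally), or < 75 % of annotated pixels.
Modal ties break to the lowest class id — harmless, because any two-way
tie is at most 50 % and fails the 75 % rule regardless. Slide-level grade
presence requires ≥ 5 % of epithelial pixels. Task mappings: low grade =
{GP3}; high grade = {GP4, Cribriform, Glomeruloid, GP5}; segmentation
target 0 = background/stroma, 1 = healthy epithelium, 2 = cancerous
epithelium. Binary probability thresholds are 0.5 everywhere.

## Folds

Patients are atomic; a shuffled patient list is dealt round-robin into
five equal groups with leftovers appended to the fifth fold. Each of 1000
seeded draws is scored by the MSE between per-fold class-count ratios and
1; a zero denominator scores +∞ so such draws are simply never selected.
The returned split is optimal over the sample (asserted in tests against
exhaustive enumeration on small instances), and patient leakage is
impossible by construction and re-asserted on every split.

## Models and training

The network engine is written in numpy inside the package: 3×3/1×1
same-padding convolutions evaluated as nine shifted BLAS products, ReLU,
2×2 max pooling, nearest upsampling, skip concatenation, dense heads,
Adam, and logit-space losses (binary cross-entropy, batch-global soft
Dice, sparse categorical cross-entropy). Initialization (he-normal or
Xavier-uniform) draws from a generator seeded at construction, so models
are bit-reproducible; epoch shuffling is seeded too.

Architectures: epithelium U-Net with four contraction / three expansion
blocks (input H×W×3, sigmoid head, Dice loss, lr 0.001, 30 epochs,
batch 32); two-channel classifier CNN of four conv/pool blocks with
global average pooling and a sigmoid unit (binary cross-entropy,
lr 0.0001, 20 epochs); cancer-segmentation U-Net with six contraction /
five expansion blocks (softmax over 3 classes, sparse categorical
cross-entropy, lr 0.02, 20 epochs). Fine-tuning keeps the architecture and
overrides the schedule (classifiers lr 2·10⁻⁵ / 20 epochs; segmentation
lr 0.01 / 10 epochs). After every epoch the validation loss is recorded;
the weights from its argmin (earliest on ties) are restored. Fold
selection takes the highest Cohen kappa (classifiers) or the highest sum
of per-class Dice scores (segmentation), earliest fold on ties.

The "full" preset keeps 256×256 inputs, 16 base filters and the full
3500-crop augmentation schedule (1000 flips half horizontal half vertical,
1500 rotations 500 per angle, 500 noise draws with variance ~ U(0, 0.5)
on the z-normalized scale, 500 blur+noise with σ ~ U(0, 5); masks are
flipped/rotated but never blurred or noised; augmented crops are generated
once per fold before training). The "desk" preset — the package's own
problem size for tests and the acceptance script — uses 64×64 inputs,
8 base filters, 12 epochs, and the same augmentation mix scaled to 140
crops, so the full demo completes in minutes on one CPU.

## Synthetic phantom

The generator renders gland-structured cores in both modalities with
pixel-perfect truth. Archetypes are deliberate caricatures chosen to make
the tasks learnable by small models, not histology: Healthy = large round
glands (wide lumen, one sparse nuclear ring), GP3 = small well-separated
glands, GP4 = fused multi-lumen clusters with dense nuclei, GP5 =
lumen-free nuclear sheets. DRAQ5 carries nuclei (~3100 of 4095 counts over
a dim textured background), Eosin carries cytoplasm (~1900) over textured
stroma (~900); the H&E rendering is the package's own Beer–Lambert map.
Glands are placed with rejection sampling until a target epithelium
coverage (45 %) or the gland budget is reached. Cohorts draw one dominant
class per core and concentrate 95 % of the gland mix on it, mirroring how
tissue-microarray cores are typically dominated by a single pattern —
fully mixed cores would make nearly every 245.52 µm crop fail the 75 %
predominance rule by construction. Default desk geometry: 512×512 px at
0.96 µm/px, so one crop is 256 px and four crops tile a core; 24 cores,
one patient each.

What the phantom does *not* emulate: nuclear chromatin texture, stain
variability beyond global casts, stromal anisotropy, imaging artifacts
other than the parametric acquisition model below. Passing tests
demonstrate that the pipeline's machinery is correct and that its
qualitative behavior (class separability, noise sensitivity) matches
expectations — not clinical performance on real tissue.

## Acquisition model and standardization

Sharpness is the mean of √(gx² + gy²) with central-difference gradients,
computed before any histogram equalization; ranking is by descending score
with ties to the earlier stack index. (On a purely monotone step edge this
score is blur-invariant — the central differences telescope — so the
sharpness tests probe textured planes, where blur genuinely lowers it.)

The forward model stands in for physically re-imaging tissue: defocus is
Gaussian blur with σ_px = k·|offset µm| (k = 0.8 px/µm); detector noise is
additive Gaussian with std = σ₀/√averaging, σ₀ defaulting to 2400 counts
so a single scan is genuinely low-SNR (~1.3 on the nuclear signal) and 8×
averaging restores ~3.7 — the regime confocal averaging exists for;
sampling density resamples linearly to the requested pitch (0.35 µm is
accepted as an alias of 0.34); the 10×/0.45 lens applies an extra PSF blur
scaled by the NA ratio 0.8/0.45 before resampling. The identity
configuration with zero noise is bit-exact. Every constant is an exposed
argument.

Registration estimates integer shifts from the argmax of the inverse
normalized cross-power spectrum; constant inputs are rejected. The
hierarchical pass tiles both rasters at 64 → 32 → 16 px, skips windows
under 1 % occupancy, caps shifts at window/4 to prevent tearing, and
applies each window's correction block-wise with a sourcing margin so no
pixels are lost at seams; shifts are not interpolated between windows.
Robustness reports re-run the full CLAHE/z-norm preprocessing per
configuration before inference and emit one long-form row per condition.

## Known limitations

* The healthy-epithelium Dice is poor at desk scale (the class is rarest
  and the desk U-Net small); background and cancer are recovered well.
* Phase correlation across modalities (binary mask vs raw intensity) is
  unreliable on the phantom's sparse textures; the registration guarantees
  are stated and tested for shifted self-pairs.
* The acquisition model is a Gaussian/linear surrogate: no optical PSF
  physics, no shot-noise statistics, no subpixel registration.
* The CLI's `full` preset instantiates the published input sizes and
  schedules but is not sized for single-CPU runs; `desk` is.
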