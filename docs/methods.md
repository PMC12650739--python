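# Methods

## Pipeline model and assumptions

The package targets bright-field micrographs containing **spatially
separated** organoids: dark, star-convex-ish bodies on a bright
background, one or a few per frame, with possibly blurred boundaries,
a dark rim at the organoid edge, uneven illumination and sensor noise.
Touching or overlapping organoids are out of scope (the area filter and
`keep="largest_component"` mode assume objects are separable), as are
fluorescence channels and stacked/multi-page images.

Segmentation is posed as two-class per-pixel classification
(background/organoid) with a third *ignore* label excluded from the loss,
used for pixels whose truth is undefined (e.g. regions introduced by
augmentation pad-back).

## Classical boundary stage

Chain order: green channel → median filter → Gaussian-derivative edge
magnitude → threshold → fill holes → erode → particle analysis. Choices
and defaults:

- **Green channel**: colour cameras carry the cleanest contrast in green;
  grayscale input passes through unchanged.
- **Median radius 1** (3×3): despeckles without rounding corners.
- **Edge detector**: gradient magnitude of the Gaussian-smoothed image at
  σ = 1 px, computed as separable correlations with a sampled Gaussian
  (sum-normalised) and its derivative (normalised to unit response on a
  unit ramp). This is a Canny-style gradient without hysteresis — the
  chain thresholds immediately, so hysteresis would be dead weight.
- **Threshold**: Otsu over 256 fixed bins on [0, 1], implemented as the
  exhaustive between-class-variance argmax (ties to the lowest cut) so
  the contract is directly testable; a fixed-threshold override exists.
  Polarity is explicit: organoids are *dark* in intensity images, edges
  are *bright* in gradient images.
- **Featureless-frame guard** (`min_edge_strength = 0.05` intensity/px):
  the edge map is max-normalised before thresholding, so a blank frame
  would otherwise have its noise floor stretched to [0, 1] and binarised
  into percolating speckle. Frames whose strongest raw gradient falls
  below the floor yield an empty mask. The floor sits an order of
  magnitude above the gradient of typical sensor noise (σ ≈ 0.03) and an
  order of magnitude below a real organoid edge step (≈ 0.2–0.5 /px).
- **Erode ×1** (3×3): the filled edge band straddles the boundary step
  nearly symmetrically (the dark rim inside the boundary pulls the band
  inward), and on noise-free synthetic frames a single erosion leaves the
  recovered mask approximately unbiased (per-frame Dice 0.98–0.99);
  two erosions measurably under-segment. The count is configurable.
- **Particle analysis**: 8-connected components (ImageJ convention),
  labelled in raster order, area-filtered at 50 px² *referenced to a
  128×128 frame* and rescaled by pixel count for other sizes. Perimeter
  uses the Crofton-formula estimator (4 directions), whose bias on
  digitised disks is a few percent — circularity is clipped at 1.
- **ROI proposals**: particle bounding boxes padded by 10 px, clipped to
  the frame.

## Network

Default `SegModelConfig`: 4 encoder levels, 3×3 kernels, filters
(8, 16, 32, 64), stride-2 max-pooling, mirrored decoder of 2×2 stride-2
transposed convolutions with skip concatenations, 1×1 head, softmax over
2 classes, single input channel (the green plane). The filter widths were
chosen so the fixed training study (below) runs in minutes on one CPU
core; they are config-exposed, as are a no-skip ablation (the plain
semantic-segmentation baseline) and a strided-convolution downsampling
mode. Inputs whose sides are not multiples of 2⁴ are reflection-padded
and the output cropped back.

All layers implement explicit forward/backward passes on numpy arrays
(windowed tensor contractions). Finite-difference directional-derivative
checks over all parameters guard every configuration; the checks jitter
the (zero-initialised) biases first, because zero bias plus ReLU-clamped
patches produces pre-activations exactly on the kink, where a central
difference measures the half-slope while backpropagation returns the
(equally valid) zero subgradient.

## Training

Adam (lr 10⁻³, β = 0.9/0.999), batch 8, masked pixel cross-entropy with
probabilities clipped at 10⁻⁷ inside the log. Augmentation applies one
seeded geometric transform per sample per epoch: 90° rotation multiples
and axis flips (exact, no interpolation), then scaling drawn from
0.9–1.1× with centre crop, or pad-back where the image gets edge values
and the labels the ignore class — the loss never sees fabricated
background. Validation runs every `val_interval` epochs and never touches
weights; the best-validation-loss state is restored at the end. With a
fixed seed the entire run (init, data order, augmentation draws) is
bit-reproducible on a given machine.

Epochs default to 300 to match a fixed-budget training regime; the
package's own study uses 40 (see below), where the loss curve has long
plateaued on synthetic data.

## ROI refinement

Two independent mechanisms, both on by default:

- **Pre-CNN ROI stage**: the classical chain's padded boxes are grown,
  within the frame, to sides that are multiples of the network's
  downsampling factor and at least 64 px, then the network runs inside
  each box and per-box foreground probabilities are pasted into the frame
  (maximum under overlap; zero outside all boxes; full-frame fallback
  when no box is found). The growth rule exists because crops that need
  reflection padding, or that are smaller than the encoder's receptive
  field, degrade predictions near crop borders (measured: mean Dice
  0.9950 vs 0.9972 on the study's test partition).
- **Post-CNN cleanup**: threshold at 0.5 → fill holes → closing with a
  radius-2 disk → drop components under the (rescaled) 50 px² floor, or
  keep only the largest. On an already-clean prediction the cleanup is a
  fixed point except for the closing of boundary concavities.

Disabling both reduces `segment` exactly to the plain semantic
segmentation baseline.

## Baselines

- **Hölder mean**: threshold at M_p of all intensities (zeros offset by
  1/255); p = 2 by default, exponent exposed since the choice is a
  convention. Dark-side-of-threshold foreground by default. The
  comparison harness reports a sweep over p ∈ {−1, 0, 1, 2, 3}.
- **K-means (k = 2, 1-D)**: default `init="exact"` computes the global
  SSE optimum by scanning the n−1 splits of the sorted intensities
  (optimal 1-D clusters are intervals); Lloyd iteration from that start
  is an immediate fixed point. Classical Lloyd from extremes or seeded
  random centres is available; it can land in local optima on small
  instances, which is why it is not the default. The darker cluster is
  foreground.
- **Plain CNN**: the no-skip backbone, trained identically, forward pass
  plus 0.5 threshold, no ROI stage, no cleanup.

## Evaluation

Accuracy, Dice and Jaccard derive from exact TP/TN/FP/FN tallies; both
masks empty defines Dice = Jaccard = 1 with a per-image degeneracy flag
so aggregates can exclude the convention. Aggregates are mean ± sample SD
(n−1) across test images; n = 1 reports SD 0 and flags the row. The
one-way ANOVA is computed from the sums-of-squares decomposition with the
F survival function; zero within-group variance with unequal means is
reported as (∞, p = 0). Comparing *different metrics on the same images*
with ANOVA violates the independence assumption — the function computes
what it is asked to, but method-vs-method comparisons on a single metric
are the supported use. No multiple-testing correction is applied.

## Synthetic data generator

Frames emulate: bright background (0.82) with a linear illumination
gradient (up to 10% drop along a seeded direction), a darker interior
(0.45), a dark rim occupying the 3 px band just inside the boundary (at
0.6 × interior level), optics blur (Gaussian, σ 0.7 px), and i.i.d.
Gaussian sensor noise (σ 0.03), clipped to [0, 1]. The boundary is a
star-convex radial-harmonic curve with 6 seeded harmonics and total
perturbation ≤ 15% of the base radius, the radius uniform in 15–35% of
the frame side, and the centre jittered while keeping the organoid fully
inside the frame. The rim is drawn *inside* the true boundary so that
with the noise switched off the inside/outside intensity histograms are
separable by a single threshold — an exact-oracle property the baseline
tests rely on — and the mask is the exact curve interior.

What the generator does **not** emulate: texture inside the organoid,
defocus point-spread asymmetry, debris and dust, vignetting beyond a
linear ramp, multiple or touching organoids, and annotation noise in the
masks. Passing tests therefore demonstrate that the pipeline's machinery
is correct and that the method ordering holds under controlled
conditions; they do not certify performance on real cultures, where
boundary texture and clutter are the dominant failure modes.

## The study configuration

All end-to-end numbers are computed at a fixed, deliberately small scale:
200 synthetic 64×64 frames, the default 70/10/20 split (140/20/40),
40 epochs, batch 8, one CPU thread, seeds fixed. At this scale the final
training pixel accuracy exceeds 0.99, held-out Dice of the proposed
pipeline exceeds 0.99, and the ordering proposed ≥ plain no-skip CNN
holds with a clear margin (≈ 0.997 vs ≈ 0.970). Intensity-only baselines
(k-means, Hölder at favourable p) are strong on this synthetic task —
noise-free class separability is built into the generator — so the CNN's
advantage shows mainly against the *plain* CNN and the unfavourable
Hölder exponents; on real data with textured interiors the gap to
intensity thresholding widens.

## Numerical choices and degenerate inputs

- Unit-interval float intensities in memory; 8-bit on disk (÷255).
- Masks on disk: 0/255 single-channel images; ignore stored as 128.
- Otsu on a constant image raises a degenerate-histogram error; k-means
  on a constant image likewise; the pipeline maps featureless frames to
  empty masks before these can trigger.
- Softmax is computed with max-subtraction; loss probabilities clipped at
  10⁻⁷; float32 parameters by default with a float64 mode used by the
  gradient checks.
- Max-pool ties route gradient to the first maximal element.
- Split rounding: ⌊0.7n⌋/⌊0.1n⌋/remainder, shuffle-then-slice, seed 42 by
  default.

## Known limitations

- One organoid per synthetic frame; the multi-object code paths (multiple
  ROIs, area filtering) are tested structurally but not against crowded
  scenes.
- The numpy network trains small models on small images efficiently but
  does not scale to megapixel frames or deep stacks; the architecture is
  intentionally compact.
- Bit-reproducibility holds for a fixed BLAS/thread configuration; exact
  weights may differ across numerical libraries, though the study's
  conclusions are insensitive to this.
- FeatureJ/ImageJ numerical parity is not attempted; the chain matches
  the operators' definitions, not their implementations.
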