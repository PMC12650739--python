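# organoidseg

Two-stage segmentation of bright-field organoid images: a classical
boundary-detection chain proposes regions of interest, an encoder–decoder
CNN labels every pixel inside them, and morphological refinement cleans
the result. The package is aimed at organoid-culture labs that need
reproducible size and morphology measurements from transmitted-light
micrographs — where organoids appear as dark, irregular, roughly
elliptical bodies on a bright background — without hand-tracing masks.

## Method

**Stage 1 — classical boundary detection.** Each frame passes through an
ImageJ-style chain: green-channel extraction, median filtering,
Gaussian-derivative edge magnitude |∇(G_σ ∗ I)|, Otsu thresholding
(exhaustive 256-bin between-class-variance maximisation), hole filling,
erosion, and 8-connected particle analysis reporting area A, perimeter P,
circularity 4πA/P², and equivalent diameter 2√(A/π). Particle bounding
boxes, padded and grown to network-friendly sizes, become ROI proposals,
and on clean frames the chain's mask itself serves as a training label.

**Stage 2 — CNN semantic segmentation.** A U-Net-style network — four
encoder levels of 3×3 convolution → ReLU → stride-2 max-pooling, a
mirrored decoder of 2×2 transposed convolutions with skip concatenations,
and a final 1×1 convolution with softmax — assigns each pixel a
background/organoid probability. Training minimises the masked pixel
cross-entropy

    L = − (1/|Ω|) Σ_{p∈Ω} log q_p(y_p),   Ω = {pixels with y_p ≠ ignore}

with Adam (lr 10⁻³), seeded geometric augmentation (90° rotations, flips,
0.9–1.1× scaling), and best-validation checkpointing. The forward and
backward passes are implemented directly on numpy arrays, so training is
deterministic and runs on a single CPU.

**Refinement.** Probabilities are thresholded at 0.5, holes filled, the
mask closed with a small disk, and components below a minimum area
dropped. With the ROI stage on, pixels outside all proposed boxes are
background by construction.

Segmentations are scored by pixel accuracy (TP+TN)/N, Dice
2TP/(2TP+FP+FN) and Jaccard TP/(TP+FP+FN), aggregated as mean ± sample
SD across test images, with a from-first-principles one-way ANOVA for
method comparisons. Hölder-mean thresholding (threshold at the power mean
M_p = ((1/n)Σvᵢᵖ)^{1/p}), exact 1-D two-class k-means, and the plain
no-skip CNN serve as baselines.

Because real annotated organoid datasets are rarely shareable, the
package ships a seeded synthetic generator: star-convex boundaries
r(θ) = r₀(1 + a·Σ aₖcos(kθ+φₖ)) with exact interior masks, dark rim,
illumination gradient, optics blur and Gaussian noise. Every claim the
test suite makes is validated against these exact masks.

## Worked example

```python
from organoidseg import (SynthParams, generate_organoid_image,
                         make_groundtruth, confusion, dice)

image, truth = generate_organoid_image(
    side=128, params=SynthParams(noise_sigma=0.01), seed=3)
mask, particles = make_groundtruth(image)
print(len(particles))                      # 1
p = particles[0]
print(round(p.area), round(p.circularity, 3), round(p.equivalent_diameter, 1))
                                           # 1480  0.929  43.4
print(round(dice(confusion(mask, truth)), 4))   # 0.9866
```

One organoid is found; its area (1480 px²), circularity (0.929 — nearly
round) and equivalent diameter (43.4 px) quantify its morphology, and the
recovered mask overlaps the exact synthetic truth with Dice 0.987.
The scripts in `examples/` walk through dataset synthesis, the classical
chain, CNN training + two-stage segmentation, and the baseline
comparison; a thin CLI (`organoidseg synth/preprocess/train/segment/
evaluate/compare`) wraps the same functions for shell use.

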