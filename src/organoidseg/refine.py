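"""Inference with ROI refinement — the stage that distinguishes the
proposed pipeline from plain semantic segmentation.

Two complementary mechanisms are provided, each independently
switchable:

* **ROI stage** (pre-CNN): the classical boundary chain proposes padded
  bounding boxes and the network runs only inside them; everything
  outside the boxes is background. With no proposal the network falls
  back to the full frame.
* **Morphological cleanup** (post-CNN): threshold -> fill holes ->
  closing -> small-component removal (or keep-largest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .classical import (PreprocessConfig, extract_green_channel, fill_holes,
                        label_particles, make_groundtruth, propose_rois,
                        scaled_min_area)
from .errors import FormatError, ParameterError
from .nn import UNet

__all__ = ["RefineConfig", "refine_mask", "segment", "overlay"]


@dataclass(frozen=True)
class RefineConfig:
    """Refinement switches and thresholds.

    ``min_component_area`` is referenced to a 128x128 frame and rescaled
    by pixel count, as in the classical stage. ``use_roi_stage`` toggles
    the pre-CNN ROI cropping; ``morphological_cleanup`` toggles the
    post-CNN mask cleanup (disable both to recover the plain
    semantic-segmentation baseline).
    """

    prob_threshold: float = 0.5
    min_component_area: float = 50.0
    closing_radius: int = 2
    keep: str = "all_above_min"  # or "largest_component"
    use_roi_stage: bool = True
    morphological_cleanup: bool = True

    def __post_init__(self):
        if not (0.0 < self.prob_threshold < 1.0):
            raise ParameterError("prob_threshold must be in (0, 1)")
        if self.closing_radius < 0 or self.min_component_area < 0:
            raise ParameterError("radii and areas must be >= 0")
        if self.keep not in {"all_above_min", "largest_component"}:
            raise ParameterError(f"unknown keep mode {self.keep!r}")


def _to_foreground_prob(probs_or_mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(probs_or_mask)
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if arr.ndim == 3:  # (H, W, K) probability map; class 1 is foreground
        return arr[..., 1].astype(np.float64)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    raise FormatError(f"unsupported input shape {arr.shape}")


def refine_mask(probs_or_mask: np.ndarray,
                config: RefineConfig | None = None) -> np.ndarray:
    """Clean a probability map or raw mask into the final binary mask.

    Threshold at ``prob_threshold`` (no-op for boolean input), then — if
    ``morphological_cleanup`` — fill holes, close with a disk of
    ``closing_radius`` and drop components below the (rescaled) minimum
    area, or keep only the largest component.
    """
    config = config or RefineConfig()
    fg = _to_foreground_prob(probs_or_mask)
    mask = fg >= config.prob_threshold
    if not config.morphological_cleanup:
        return mask
    mask = fill_holes(mask)
    if config.closing_radius > 0:
        se = disk(config.closing_radius)
        mask = ndi.binary_erosion(
            ndi.binary_dilation(mask, structure=se), structure=se,
            border_value=1,
        )
    min_area = scaled_min_area(config.min_component_area, mask.shape)
    labels, stats = label_particles(mask, min_area=0.0)
    if not stats:
        return np.zeros_like(mask)
    if config.keep == "largest_component":
        best = max(stats, key=lambda s: s.area)
        return labels == best.label
    keep_labels = [s.label for s in stats if s.area >= min_area]
    return np.isin(labels, keep_labels)


#: crops below the encoder's receptive field starve the network of the
#: context it was trained with, so ROI boxes are never smaller than this
MIN_ROI_SIDE = 64


def _snap_box(box, frame, factor):
    """Grow a box within the frame so its sides are multiples of ``factor``
    (the network's downsampling stride) and at least :data:`MIN_ROI_SIDE`,
    avoiding pad artefacts and context loss in crops."""
    top, left, h, w = box
    H, W = frame
    nh = min(H, -(-max(h, MIN_ROI_SIDE) // factor) * factor)
    nw = min(W, -(-max(w, MIN_ROI_SIDE) // factor) * factor)
    top = max(0, min(top - (nh - h) // 2, H - nh))
    left = max(0, min(left - (nw - w) // 2, W - nw))
    return top, left, nh, nw


def segment(model: UNet, image: np.ndarray,
            refine: RefineConfig | None = None,
            preprocess: PreprocessConfig | None = None) -> np.ndarray:
    """Segment one frame with the full two-stage pipeline.

    With the ROI stage enabled, the classical chain proposes padded boxes
    (grown to stride-multiple sizes within the frame) and the network is
    applied inside each; per-box foreground probabilities are pasted into
    a full-frame map (maximum where boxes overlap, zero outside all
    boxes). Without proposals — or with ``use_roi_stage=False`` — the
    network runs on the full frame. The refinement of :func:`refine_mask`
    is then applied.
    """
    refine = refine or RefineConfig()
    preprocess = preprocess or PreprocessConfig()
    chan = extract_green_channel(np.asarray(image))
    H, W = chan.shape

    boxes = []
    if refine.use_roi_stage:
        _, stats = make_groundtruth(image, preprocess)
        boxes = propose_rois(stats, preprocess.roi_margin, (H, W))
        boxes = [_snap_box(b, (H, W), model._factor) for b in boxes]

    if boxes:
        fg = np.zeros((H, W), dtype=np.float64)
        for top, left, h, w in boxes:
            probs = model.forward(chan[top:top + h, left:left + w])
            np.maximum(fg[top:top + h, left:left + w], probs[..., 1],
                       out=fg[top:top + h, left:left + w])
    else:
        fg = model.forward(chan)[..., 1]
    return refine_mask(fg, refine)


def overlay(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RGB copy of ``image`` with the mask boundary painted pure green.

    The boundary is the morphological inner boundary: mask minus its
    3x3 erosion (frame border pixels of the mask count as boundary).
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise FormatError("image and mask must share their spatial size")
    if image.ndim == 2:
        rgb = np.stack([image] * 3, axis=-1).astype(np.float32)
    else:
        rgb = image.astype(np.float32).copy()
    boundary = mask & ~ndi.binary_erosion(mask, structure=np.ones((3, 3)),
                                          border_value=0)
    rgb[boundary] = (0.0, 1.0, 0.0)
    return rgb
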