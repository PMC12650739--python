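"""Image and dataset I/O.

Conventions used throughout the package:

* images live in memory as float arrays in the unit interval, shape
  ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB; on disk they are
  8-bit TIFF or PNG (values ``0..255``),
* binary masks are boolean ``(H, W)`` arrays; on disk single-channel
  8-bit images with 0 = background and 255 = foreground,
* label maps are small-integer ``(H, W)`` arrays with classes
  0 = background, 1 = organoid and :data:`IGNORE` = undefined; on disk
  the ignore label is stored as 128,
* coordinates are row-major, 0-based, origin at the top-left corner.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from .errors import FormatError, ParameterError

#: label value marking pixels excluded from the loss during training
IGNORE = 2

#: on-disk encoding of the three label classes
_LABEL_TO_BYTE = {0: 0, 1: 255, IGNORE: 128}
_BYTE_TO_LABEL = {0: 0, 255: 1, 128: IGNORE}


# ---------------------------------------------------------------------------
# single-image I/O
# ---------------------------------------------------------------------------

def _imread(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(path) -> np.ndarray:
    """Read an 8-bit TIFF/PNG image and normalise it to the unit interval.

    Channel count is preserved (grayscale stays ``(H, W)``, RGB stays
    ``(H, W, 3)``); an RGBA alpha channel is dropped.
    """
    arr = _imread(Path(path))
    if arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise FormatError(
            f"unsupported bit depth: {arr.dtype} (only 8-bit images are supported)"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported image layout: shape {arr.shape}")
    return arr.astype(np.float32) / 255.0


def write_image(path, image: np.ndarray) -> None:
    """Write a unit-interval image as 8-bit TIFF or PNG (by extension)."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    data = np.rint(arr * 255.0).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_mask(path) -> np.ndarray:
    """Read a binary mask (single-channel 8-bit image, 0/255)."""
    arr = _imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return np.asarray(arr) > 127


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a single-channel 8-bit image (0/255)."""
    write_image(path, np.asarray(mask, dtype=bool).astype(np.float32))


def read_labels(path) -> np.ndarray:
    """Read a label map stored with the 0/128/255 byte encoding."""
    arr = _imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    out = np.zeros(arr.shape, dtype=np.int8)
    out[arr > 191] = 1
    out[(arr > 63) & (arr <= 191)] = IGNORE
    return out


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    data = np.zeros(labels.shape, dtype=np.uint8)
    for lab, byte in _LABEL_TO_BYTE.items():
        data[labels == lab] = byte
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def mask_to_labels(mask: np.ndarray) -> np.ndarray:
    """Binary mask -> {0, 1} label map (no ignore pixels)."""
    return np.asarray(mask, dtype=bool).astype(np.int8)


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a unit-interval image (anti-aliased when shrinking)."""
    if image.shape[:2] == tuple(shape):
        return image
    out = _sk_resize(
        np.asarray(image, dtype=np.float64),
        shape,
        order=1,
        mode="edge",
        anti_aliasing=min(shape) < min(image.shape[:2]),
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; output stays strictly binary."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == tuple(shape):
        return mask
    out = _sk_resize(
        mask.astype(np.uint8), shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return out.astype(bool)


def resize_pair(image: np.ndarray, mask: np.ndarray, side: int):
    """Resize an image/mask pair to ``side x side``.

    The image is interpolated bilinearly; the mask with nearest-neighbour
    so it remains binary. A pair already at the target size is returned
    unchanged (pixel-identical).
    """
    if side < 8:
        raise ParameterError(f"side must be >= 8, got {side}")
    return resize_image(image, (side, side)), resize_mask(mask, (side, side))


# ---------------------------------------------------------------------------
# paired datasets and the train/val/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetItem:
    id: str
    image_path: Path
    mask_path: Path


@dataclass
class PairedDataset:
    """An ordered collection of image/mask pairs plus the working patch size.

    ``patch_size`` is the side length pairs are resized to when loaded for
    training (240 in the original study) or testing (128).
    """

    items: list[DatasetItem] = field(default_factory=list)
    patch_size: int = 240

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __post_init__(self):
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ParameterError("dataset ids must be unique")

    def load_pair(self, item_id: str, side: int | None = None):
        """Load one (image, mask) pair, optionally resized to ``side``."""
        item = next(it for it in self.items if it.id == item_id)
        image = read_image(item.image_path)
        mask = read_mask(item.mask_path)
        if image.shape[:2] != mask.shape:
            raise FormatError(
                f"image/mask size mismatch for id {item_id}: "
                f"{image.shape[:2]} vs {mask.shape}"
            )
        if side is not None:
            image, mask = resize_pair(image, mask, side)
        return image, mask

    def to_manifest(self, path, split: "DatasetSplit | None" = None) -> None:
        """Write the CSV manifest (columns: id,image_path,mask_path,split)."""
        assignment = {}
        if split is not None:
            for name, ids in (
                ("train", split.train_ids),
                ("val", split.val_ids),
                ("test", split.test_ids),
            ):
                for i in ids:
                    assignment[i] = name
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "image_path", "mask_path", "split"])
            for it in self.items:
                writer.writerow(
                    [it.id, str(it.image_path), str(it.mask_path),
                     assignment.get(it.id, "")]
                )

    @classmethod
    def from_manifest(cls, path, patch_size: int = 240) -> "PairedDataset":
        base = Path(path).parent
        items = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                img = Path(row["image_path"])
                msk = Path(row["mask_path"])
                if not img.is_absolute():
                    img = base / img
                if not msk.is_absolute():
                    msk = base / msk
                items.append(DatasetItem(row["id"], img, msk))
        return cls(items=items, patch_size=patch_size)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test id lists produced by :func:`split_dataset`."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    seed: int = 42

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ParameterError("split partitions overlap")


def split_dataset(
    ds: PairedDataset,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 42,
) -> DatasetSplit:
    """Shuffle-then-slice split into train/validation/test partitions.

    Sizes follow a fixed rounding rule: ``|train| = floor(f_train * n)``,
    ``|val| = floor(f_val * n)``, and the test partition receives the
    remainder, so the three lists always partition the dataset exactly.
    Deterministic for a given seed.
    """
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f <= 0 for f in fr):
        raise ParameterError(f"fractions must be three positive values, got {fr}")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {sum(fr)!r}")
    ids = np.array(ds.ids, dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = ids[perm]
    n = len(ids)
    n_train = math.floor(fr[0] * n + 1e-9)
    n_val = math.floor(fr[1] * n + 1e-9)
    return DatasetSplit(
        train_ids=list(shuffled[:n_train]),
        val_ids=list(shuffled[n_train:n_train + n_val]),
        test_ids=list(shuffled[n_train + n_val:]),
        fractions=fr,
        seed=seed,
    )
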