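"""Data pipeline for Data-Science-Bowl-style nuclei datasets.

Reads the folder-per-image layout (``<imageId>/images/*.png`` plus
``<imageId>/masks/*.png`` with one binary mask per nucleus and a strict
no-overlap rule), merges instance masks into a binary union and an integer
label image, normalizes images (grayscale, resize, histogram equalization,
min–max), refines masks morphologically, encodes/decodes the 1-based
column-major run-length submission dialect, and provides stratified
splitting, k-fold cross-validation indices, inverse-frequency sample
weights and seeded train-time augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, morphology, transform

#: ITU-R 601 luminance weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """One sample: image, per-instance masks, merged mask, stratum, weight."""

    image_id: str
    image: np.ndarray
    instance_masks: list[np.ndarray] = field(default_factory=list)
    merged_mask: np.ndarray | None = None
    label_image: np.ndarray | None = None
    stratum: str = "unknown"
    weight: float = 1.0
    labeled: bool = True


@dataclass
class SplitSpec:
    """Fractions, fold count and seed for deterministic stratified splitting."""

    train: float = 0.8
    validation: float = 0.1
    test: float = 0.1
    k: int = 5
    seed: int = 0
    stratify_on: str = "stratum"

    def __post_init__(self):
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.k < 2:
            raise ValueError("fold count must be >= 2")


# ---------------------------------------------------------------------------
# reading the folder layout

def _read_binary_png(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def read_dsb_tree(root: str | Path, strata: dict[str, str] | None = None) -> list[ImageRecord]:
    """Load every image id under ``root``; deterministic lexicographic order.

    Trees without ``masks`` folders (test phase) yield records flagged
    unlabeled.  Overlapping instance masks raise a validation error naming
    the offending image id.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        images_dir = d / "images"
        if not images_dir.is_dir():
            raise IOError(f"{d.name}: missing images folder")
        image_files = sorted(images_dir.iterdir())
        if not image_files:
            raise IOError(f"{d.name}: images folder is empty")
        image = iio.imread(image_files[0])
        masks_dir = d / "masks"
        rec = ImageRecord(image_id=d.name, image=image)
        if masks_dir.is_dir():
            masks = [_read_binary_png(f) for f in sorted(masks_dir.iterdir())]
            for m in masks:
                if m.shape != image.shape[:2]:
                    raise ValueError(f"{d.name}: mask shape {m.shape} does not "
                                     f"match image {image.shape[:2]}")
            try:
                merged, labels = merge_instance_masks(masks)
            except ValueError as e:
                raise ValueError(f"{d.name}: {e}") from e
            rec.instance_masks = masks
            rec.merged_mask = merged
            rec.label_image = labels
        else:
            rec.labeled = False
        if strata and d.name in strata:
            rec.stratum = strata[d.name]
        records.append(rec)
    return records


def merge_instance_masks(masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Union of disjoint instance masks plus an integer label image
    (0 = background, i = i-th instance, 1-based)."""
    if not masks:
        return np.zeros((0, 0), dtype=np.uint8), np.zeros((0, 0), dtype=np.int32)
    shape = masks[0].shape
    merged = np.zeros(shape, dtype=np.uint8)
    labels = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(masks, start=1):
        b = np.asarray(m).astype(bool)
        if b.shape != shape:
            raise ValueError("instance masks differ in shape")
        if (merged.astype(bool) & b).any():
            raise ValueError("instance masks overlap; each pixel must belong "
                             "to at most one mask")
        merged[b] = 1
        labels[b] = i
    return merged, labels


# ---------------------------------------------------------------------------
# image preprocessing

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale conversion; drops an alpha channel."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        if img.shape[-1] == 4:
            img = img[..., :3]
        if img.shape[-1] == 3:
            img = img @ _LUMA
        else:
            img = img[..., 0]
    return img


def preprocess_image(image: np.ndarray, target_size: int = 256,
                     equalize: bool = True) -> np.ndarray:
    """Grayscale -> resize -> histogram equalization -> min–max to [0, 1].

    A constant image degenerates under min–max scaling and comes back as all
    zeros (with a warning).
    """
    if np.asarray(image).size == 0:
        raise ValueError("empty image")
    img = to_grayscale(image)
    img = transform.resize(img, (target_size, target_size), order=1,
                           preserve_range=True, anti_aliasing=True)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        warnings.warn("constant image: min–max normalization degenerates to zeros")
        return np.zeros_like(img)
    if equalize:
        img = exposure.equalize_hist(img)
        lo, hi = float(img.min()), float(img.max())
        if hi - lo < 1e-12:
            return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def resize_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbour resize keeping the mask strictly binary."""
    out = transform.resize(mask.astype(np.uint8), (target_size, target_size),
                           order=0, preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def refine_mask(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological opening then closing with a disk element; removes specks
    smaller than the element and is idempotent on re-application."""
    b = np.asarray(mask).astype(bool)
    selem = morphology.disk(radius)
    out = morphology.closing(morphology.opening(b, selem), selem)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# run-length codec (submission dialect: 1-based, column-major)

@dataclass(frozen=True)
class RleString:
    """Run-length encoding of one binary mask: space-separated
    ``start length`` pairs over 1-based column-major pixel numbering."""

    text: str
    shape: tuple[int, int]

    def tokens(self) -> list[int]:
        return [int(t) for t in self.text.split()]


def rle_encode(mask: np.ndarray) -> RleString:
    """Encode a binary mask; runs are maximal and listed in increasing start order."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    flat = m.flatten(order="F").astype(bool)
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    pairs = []
    for s, e in zip(starts, ends):
        pairs += [str(s + 1), str(e - s)]
    return RleString(text=" ".join(pairs), shape=m.shape)


def rle_decode(rle: RleString) -> np.ndarray:
    """Decode to a binary mask; malformed or overlapping runs raise with the
    offending token position."""
    tokens = rle.text.split()
    if len(tokens) % 2:
        raise ValueError(f"odd token count ({len(tokens)}): RLE must pair "
                         "starts with lengths")
    h, w = rle.shape
    n = h * w
    flat = np.zeros(n, dtype=np.uint8)
    prev_end = 0
    for idx in range(0, len(tokens), 2):
        try:
            start, run = int(tokens[idx]), int(tokens[idx + 1])
        except ValueError as e:
            raise ValueError(f"non-integer token at position {idx}") from e
        if start < 1 or run < 1:
            raise ValueError(f"non-positive start/length at token {idx}")
        if start <= prev_end:
            raise ValueError(f"overlapping or unordered run at token {idx}")
        if start - 1 + run > n:
            raise ValueError(f"run at token {idx} exceeds {h}x{w} image")
        flat[start - 1:start - 1 + run] = 1
        prev_end = start - 1 + run
    return flat.reshape((h, w), order="F")


def write_submission(rows: list[tuple[str, RleString]], path: str | Path) -> None:
    """Write an ``ImageId,EncodedPixels`` submission CSV."""
    df = pd.DataFrame({"ImageId": [r[0] for r in rows],
                       "EncodedPixels": [r[1].text for r in rows]})
    df.to_csv(path, index=False)


def read_submission(path: str | Path, shapes: dict[str, tuple[int, int]]
                    ) -> dict[str, np.ndarray]:
    """Read a submission CSV back into masks, given per-image shapes."""
    df = pd.read_csv(path, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        image_id = str(row["ImageId"])
        out[image_id] = rle_decode(RleString(str(row["EncodedPixels"]),
                                             shapes[image_id]))
    return out


# ---------------------------------------------------------------------------
# splitting, folds, weights

def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n items to three groups."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_split(records: list[ImageRecord], spec: SplitSpec
                     ) -> tuple[list[int], list[int], list[int]]:
    """Disjoint exhaustive train/validation/test index sets, per-stratum
    proportions within one sample of the requested fractions, deterministic
    under the configured seed."""
    rng = np.random.default_rng(spec.seed)
    strata: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(getattr(rec, spec.stratify_on), []).append(i)
    train, val, test = [], [], []
    for label in sorted(strata):
        idx = np.array(strata[label])
        if len(idx) < 3:
            warnings.warn(f"stratum {label!r} has only {len(idx)} records; "
                          "best-effort assignment")
        rng.shuffle(idx)
        n_tr, n_va, n_te = _allocate(len(idx), (spec.train, spec.validation, spec.test))
        train += idx[:n_tr].tolist()
        val += idx[n_tr:n_tr + n_va].tolist()
        test += idx[n_tr + n_va:].tolist()
    return sorted(train), sorted(val), sorted(test)


def kfold_indices(n: int, spec: SplitSpec,
                  strata: list[str] | None = None
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """k stratified (train, held-out) index pairs; each index held out once."""
    if n < spec.k:
        raise ValueError(f"cannot make {spec.k} folds from {n} records")
    from sklearn.model_selection import KFold, StratifiedKFold
    if strata is not None:
        counts = pd.Series(strata).value_counts()
        if (counts < spec.k).any():
            warnings.warn("some strata are smaller than the fold count; "
                          "falling back to unstratified folds")
            splitter = KFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
            return list(splitter.split(np.arange(n)))
        splitter = StratifiedKFold(n_splits=spec.k, shuffle=True,
                                   random_state=spec.seed)
        return list(splitter.split(np.arange(n), strata))
    splitter = KFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
    return list(splitter.split(np.arange(n)))


def sample_weights(records: list[ImageRecord]) -> np.ndarray:
    """Inverse-stratum-frequency weights normalized to mean 1; also written
    back onto the records."""
    labels = [r.stratum for r in records]
    counts = pd.Series(labels).value_counts()
    w = np.array([1.0 / counts[lab] for lab in labels], dtype=np.float64)
    w *= len(w) / w.sum()
    for rec, wi in zip(records, w):
        rec.weight = float(wi)
    return w


# ---------------------------------------------------------------------------
# augmentation

def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            elastic: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Random flips, 90-degree rotations, multiplicative intensity jitter
    (±10%) and a small affine warp; the identical geometric transform is
    applied to image and mask, and the mask stays binary."""
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError("image and mask shapes differ")
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]
    k = int(rng.integers(0, 4))
    if k:
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    img = np.clip(img * (1.0 + rng.uniform(-0.1, 0.1)), 0.0, 1.0)
    if elastic and rng.random() < 0.5:
        h, w = img.shape[:2]
        angle = rng.uniform(-10, 10) * np.pi / 180.0
        scale = rng.uniform(0.95, 1.05)
        c, s = np.cos(angle) * scale, np.sin(angle) * scale
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        ys = c * (yy - cy) - s * (xx - cx) + cy
        xs = s * (yy - cy) + c * (xx - cx) + cx
        img = ndimage.map_coordinates(img, [ys, xs], order=1, mode="reflect")
        msk = ndimage.map_coordinates(msk.astype(np.float64), [ys, xs],
                                      order=0, mode="reflect")
    return np.ascontiguousarray(img), np.ascontiguousarray(
        (msk > 0.5).astype(np.uint8))
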