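"""Seeded synthetic nuclei-image generator in the DSB folder layout.

Scenes are fields of elliptical "nuclei" on a contrasting background:
centers are placed by rejection sampling (an ``overlap_pressure`` knob
shrinks the required center separation, so crowded scenes have touching
cells), pixels contended by two ellipses are assigned to the nearer center
so instance masks are pairwise disjoint by construction, and the rendered
intensity image gets Gaussian blur and noise before clipping to [0, 1].
Both intensity polarities of real microscopy (fluorescence-style bright
nuclei on dark, brightfield-style dark nuclei on bright) are emulated.

Everything is a deterministic function of (spec, seed).  What this emulates
— and what it does not (texture, stain chemistry, uneven illumination) — is
discussed in the methods note.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .pipeline import ImageRecord, merge_instance_masks

#: instance-count boundaries of the density terciles used as stratum labels
DENSITY_BINS = (8, 16)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    image_size: int = 256
    n_instances: int | tuple[int, int] = (8, 24)
    axis_range: tuple[float, float] = (6.0, 16.0)      # major semi-axis, px
    eccentricity_range: tuple[float, float] = (0.0, 0.8)
    foreground_range: tuple[float, float] = (0.55, 0.9)
    background_range: tuple[float, float] = (0.05, 0.25)
    polarity: str = "bright_on_dark"
    overlap_pressure: float = 0.3
    blur_sigma: float = 1.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.polarity not in ("bright_on_dark", "dark_on_bright"):
            raise ValueError("polarity must be bright_on_dark or dark_on_bright")
        for name in ("axis_range", "eccentricity_range", "foreground_range",
                     "background_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")
        lo = self.n_instances if isinstance(self.n_instances, int) else self.n_instances[0]
        if lo < 0:
            raise ValueError("n_instances must be >= 0")
        if not 0.0 <= self.overlap_pressure <= 1.0:
            raise ValueError("overlap_pressure must lie in [0, 1]")


def scaled_default_spec(image_size: int, seed: int = 0) -> SceneSpec:
    """Default scene conditions scaled from the 256-pixel reference frame so
    small desk-scale images stay feasible to populate."""
    f = image_size / 256.0
    lo = max(2, int(round(8 * f * f)))
    hi = max(lo + 2, int(round(24 * f * f)))
    return SceneSpec(image_size=image_size,
                     n_instances=(lo, hi),
                     axis_range=(max(3.0, 6.0 * f), max(5.0, 16.0 * f)),
                     seed=seed)


def density_class(n_instances: int) -> str:
    if n_instances < DENSITY_BINS[0]:
        return "low"
    if n_instances < DENSITY_BINS[1]:
        return "mid"
    return "high"


def stratum_label(spec_polarity: str, n_instances: int) -> str:
    return f"{spec_polarity}:{density_class(n_instances)}"


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class PlacementError(RuntimeError):
    """Raised when the requested number of instances cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        self.requested, self.achieved = requested, achieved
        super().__init__(f"placed only {achieved} of {requested} instances "
                         "before exhausting attempts")


def render_scene(spec: SceneSpec) -> ImageRecord:
    """Render one scene: image in [0, 1] plus exact disjoint instance masks."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    if isinstance(spec.n_instances, int):
        n = spec.n_instances
    else:
        n = int(rng.integers(spec.n_instances[0], spec.n_instances[1] + 1))

    centers: list[tuple[float, float]] = []
    majors: list[float] = []
    params = []
    attempts, max_attempts = 0, max(200, 60 * max(n, 1))
    while len(params) < n and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(*spec.axis_range)
        e = rng.uniform(*spec.eccentricity_range)
        b = a * np.sqrt(1.0 - e ** 2)
        theta = rng.uniform(0.0, np.pi)
        margin = a + 1
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        ok = True
        for (py, px), pa in zip(centers, majors):
            sep = (1.0 - spec.overlap_pressure) * (a + pa)
            if (cy - py) ** 2 + (cx - px) ** 2 < sep ** 2:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            majors.append(a)
            params.append((cy, cx, a, b, theta))
    if len(params) < n:
        raise PlacementError(n, len(params))

    # nearest-center assignment of contested pixels keeps masks disjoint
    labels = np.zeros((size, size), dtype=np.int32)
    best = np.full((size, size), np.inf)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for i, (cy, cx, a, b, theta) in enumerate(params, start=1):
        inside = _ellipse_mask(size, cy, cx, a, b, theta)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        claim = inside & (d2 < best)
        labels[claim] = i
        best[claim] = d2[claim]

    instance_masks = []
    for i in range(1, len(params) + 1):
        m = (labels == i).astype(np.uint8)
        if m.any():
            instance_masks.append(m)

    if spec.polarity == "bright_on_dark":
        fg_range, bg_range = spec.foreground_range, spec.background_range
    else:
        fg_range, bg_range = spec.background_range, spec.foreground_range
    image = np.full((size, size), rng.uniform(*bg_range))
    for m in instance_masks:
        image[m.astype(bool)] = rng.uniform(*fg_range)
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    merged, label_img = merge_instance_masks(instance_masks)
    if not instance_masks:
        merged = np.zeros((size, size), dtype=np.uint8)
        label_img = np.zeros((size, size), dtype=np.int32)
    return ImageRecord(image_id=f"synthetic-{spec.seed:08d}", image=image,
                       instance_masks=instance_masks, merged_mask=merged,
                       label_image=label_img,
                       stratum=stratum_label(spec.polarity, len(instance_masks)))


def generate_dataset(n_images: int, template: SceneSpec, seed: int,
                     out_dir: str | Path, force: bool = False,
                     polarities: tuple[str, ...] = ("bright_on_dark",
                                                    "dark_on_bright")) -> pd.DataFrame:
    """Write ``n_images`` scenes in the DSB folder layout plus a manifest CSV.

    Per-image polarity cycles through ``polarities`` and per-image seeds
    derive deterministically from ``seed``, so identical calls produce
    identical trees and manifests.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} is not empty (use force=True)")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n_images):
        scene_seed = (seed + 7919 * (i + 1)) % (2 ** 31)
        spec = replace(template, seed=scene_seed,
                       polarity=polarities[i % len(polarities)])
        rec = render_scene(spec)
        image_id = f"syn{i:04d}_{scene_seed:08d}"
        d = out_dir / image_id
        (d / "images").mkdir(parents=True)
        (d / "masks").mkdir()
        iio.imwrite(d / "images" / f"{image_id}.png",
                    (rec.image * 255).round().astype(np.uint8))
        for j, m in enumerate(rec.instance_masks):
            iio.imwrite(d / "masks" / f"mask{j:03d}.png", m * 255)
        rows.append({"image_id": image_id, "stratum": rec.stratum,
                     "n_instances": len(rec.instance_masks)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def degradation_suite(base: SceneSpec,
                      polarities: tuple[str, ...] | None = None,
                      densities: tuple[int, ...] | None = None,
                      pressures: tuple[float, ...] | None = None,
                      noises: tuple[float, ...] | None = None) -> list[SceneSpec]:
    """Deterministic grid of stress variants of ``base``.

    Axes left as ``None`` stay at the base value; the grid is the Cartesian
    product of the provided axes in (polarity, density, pressure, noise)
    order.  Child seeds derive from the base seed by the same rule
    :func:`generate_dataset` uses.
    """
    pol = polarities if polarities is not None else (base.polarity,)
    den = densities if densities is not None else (None,)
    pre = pressures if pressures is not None else (base.overlap_pressure,)
    noi = noises if noises is not None else (base.noise_sigma,)
    specs = []
    i = 0
    for p in pol:
        for d in den:
            for op in pre:
                for ns in noi:
                    i += 1
                    spec = replace(
                        base, polarity=p, overlap_pressure=op, noise_sigma=ns,
                        seed=(base.seed + 7919 * i) % (2 ** 31))
                    if d is not None:
                        spec = replace(spec, n_instances=d)
                    specs.append(spec)
    return specs


def mean_adjacency(record: ImageRecord, radius: int = 1) -> float:
    """Fraction of instance-boundary pixels adjacent to a different instance:
    a crowding measure that grows with overlap pressure."""
    labels = record.label_image
    if labels is None or labels.max() < 2:
        return 0.0
    touch = 0
    border = 0
    fp = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    for i in range(1, labels.max() + 1):
        m = labels == i
        if not m.any():
            continue
        dil = ndimage.binary_dilation(m, structure=fp)
        ring = dil & ~m
        border += int(ring.sum())
        touch += int(((labels > 0) & (labels != i) & ring).sum())
    return touch / border if border else 0.0
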