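"""Mosaic structures, border-band ground truth, and textured mosaic assembly.

A mosaic structure is a partition of the image plane into integer-labeled
regions.  Three structure families are provided:

* Voronoi: 2-10 random centroids, each pixel labeled by its nearest centroid.
* Random walk: one or two monotone jittered paths crossing the image, whose
  intersection cells form 2-4 regions.
* Circular: up to four random circles over a background, giving 2-5 regions.

The binary ground truth marks the *border band*: a pixel is border when the
(2r+1) x (2r+1) Chebyshev window around it contains two or more distinct
region labels, so a straight boundary produces a band 2r pixels wide (4 with
the default r=2, i.e. always more than two pixels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .augment import AugmentConfig, augment_texture
from .errors import ConfigurationError, InputError
from .textures import TextureImage, TextureLibrary, sample_texture

STRUCTURE_TYPES = ("voronoi", "random_walk", "circular")

DEFAULT_BORDER_RADIUS = 2


@dataclass(frozen=True)
class RegionLabelMap:
    """Per-pixel region ids in [0, n_regions); every label occurs at least once."""

    labels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        lab = np.ascontiguousarray(self.labels)
        if lab.ndim != 2:
            raise InputError(f"labels must be 2-D, got shape {lab.shape}")
        present = np.unique(lab)
        if present.min() < 0 or present.max() >= self.n_regions:
            raise InputError("labels out of range [0, n_regions)")
        if len(present) != self.n_regions:
            raise InputError("every label in [0, n_regions) must occur")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class BorderMask:
    """Binary border-band ground truth (1 = border) with its window radius."""

    mask: np.ndarray
    border_radius: int = DEFAULT_BORDER_RADIUS

    def __post_init__(self) -> None:
        m = np.ascontiguousarray(self.mask).astype(np.uint8)
        if m.ndim != 2:
            raise InputError(f"mask must be 2-D, got shape {m.shape}")
        if not np.isin(m, (0, 1)).all():
            raise InputError("mask values must be binary {0, 1}")
        if self.border_radius < 1:
            raise InputError("border_radius must be >= 1")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class MosaicSample:
    """A textured mosaic with its ground truth and provenance."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    target: BorderMask
    structure: RegionLabelMap
    structure_type: str
    texture_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.target.shape or self.image.shape[:2] != self.structure.shape:
            raise InputError("image, target and structure sizes must agree")


@dataclass
class DatasetManifest:
    """Index of a mosaic dataset on disk: (image path, mask path, provenance)."""

    entries: list[dict]
    split: str = "train"
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [(e["image"], e["mask"]) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise InputError("manifest entries must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(json.dumps({"split": self.split, "seed": self.seed}) + "\n")
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        with path.open() as fh:
            lines = [json.loads(line) for line in fh if line.strip()]
        if not lines:
            raise InputError(f"empty manifest: {path}")
        header, entries = lines[0], lines[1:]
        return cls(entries=entries, split=header.get("split", "train"), seed=header.get("seed", 0))


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------

def voronoi_structure(
    size: tuple[int, int], n_centroids: int, rng: np.random.Generator
) -> RegionLabelMap:
    """Label each pixel by its nearest of ``n_centroids`` random centroids.

    Distances are Euclidean between pixel centers; ties break toward the
    lowest centroid index.  Centroids are redrawn until pairwise distinct, so
    every label occurs (each centroid is nearest to its own pixel).
    """
    if not 2 <= n_centroids <= 10:
        raise ConfigurationError(f"n_centroids must be in [2, 10], got {n_centroids}")
    H, W = size
    while True:
        pts = np.stack(
            [rng.integers(0, H, size=n_centroids), rng.integers(0, W, size=n_centroids)],
            axis=1,
        )
        if len(np.unique(pts, axis=0)) == n_centroids:
            break
    rows, cols = np.mgrid[0:H, 0:W]
    d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)  # argmin takes the lowest index on ties
    return RegionLabelMap(labels=labels.astype(np.int32), n_regions=n_centroids)


def _monotone_walk(n_steps: int, width: int, start: int, rng: np.random.Generator,
                   jitter: Sequence[int] = (-1, 0, 1)) -> np.ndarray:
    """Lateral positions of a walk advancing one step per row/column."""
    pos = np.empty(n_steps, dtype=np.int64)
    pos[0] = start
    jitter = np.asarray(jitter)
    steps = jitter[rng.integers(0, len(jitter), size=n_steps - 1)]
    pos[1:] = np.clip(start + np.cumsum(steps), 0, width - 1)
    return pos


def random_walk_structure(
    size: tuple[int, int],
    rng: np.random.Generator,
    mode: str = "two",
    jitter: Sequence[int] = (-1, 0, 1),
) -> RegionLabelMap:
    """Partition the image with one or two monotone random-walk paths.

    One path enters on the top or bottom edge and advances one row per step
    with lateral jitter until it reaches the opposite edge; the other is the
    analogous left/right walk.  Each path splits the image in two; with
    ``mode="two"`` (default) the intersection cells give 2-4 regions,
    ``mode="single"`` keeps only the vertical-travel walk (2 regions).
    """
    H, W = size
    if H < 16 or W < 16:
        raise InputError(f"size must be >= 16x16, got {size}")
    if mode not in ("two", "single"):
        raise ConfigurationError(f"mode must be 'two' or 'single', got {mode!r}")

    while True:
        # vertical-travel walk: per-row column; flip direction half the time
        col_path = _monotone_walk(H, W, int(rng.integers(0, W)), rng, jitter)
        if rng.integers(2):  # entered at the bottom edge
            col_path = col_path[::-1]
        cols = np.arange(W)
        side_a = cols[None, :] >= col_path[:, None]  # (H, W)

        if mode == "single":
            labels = side_a.astype(np.int32)
        else:
            row_path = _monotone_walk(W, H, int(rng.integers(0, H)), rng, jitter)
            if rng.integers(2):
                row_path = row_path[::-1]
            rows = np.arange(H)
            side_b = rows[:, None] >= row_path[None, :]  # (H, W)
            labels = side_a.astype(np.int32) * 2 + side_b.astype(np.int32)

        # compact to consecutive labels; empty intersection cells may drop out
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(H, W).astype(np.int32)
        if labels.max() > 0:  # a path hugging an image edge can leave one region
            return RegionLabelMap(labels=labels, n_regions=int(labels.max()) + 1)


def circular_structure(
    size: tuple[int, int],
    rng: np.random.Generator,
    max_circles: int = 4,
    max_attempts: int = 100,
) -> RegionLabelMap:
    """Up to four random circles over a background.

    Label 0 is the background; circles are painted in draw order so later
    circles overwrite earlier ones where they overlap.  Radii are drawn in
    [min(H,W)/8, min(H,W)/3].  If any circle ends up fully covered (or the
    background vanishes) the layout is redrawn so every label survives.
    """
    H, W = size
    if H < 16 or W < 16:
        raise InputError(f"size must be >= 16x16, got {size}")
    m = min(H, W)
    rows, cols = np.mgrid[0:H, 0:W]
    for _ in range(max_attempts):
        k = int(rng.integers(1, max_circles + 1))
        labels = np.zeros((H, W), dtype=np.int32)
        for i in range(k):
            cy = rng.uniform(0, H)
            cx = rng.uniform(0, W)
            r = rng.uniform(m / 8.0, m / 3.0)
            inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= r * r
            labels[inside] = i + 1
        if len(np.unique(labels)) == k + 1:
            return RegionLabelMap(labels=labels, n_regions=k + 1)
    raise InputError("could not draw a circular structure with all labels visible")


def border_mask(structure: RegionLabelMap, border_radius: int = DEFAULT_BORDER_RADIUS) -> BorderMask:
    """Border band: pixels whose Chebyshev window sees >= 2 distinct labels.

    Implemented as a max-filter/min-filter inequality over the (2r+1)-sized
    square window; nearest-edge padding makes the window clip at image edges.
    """
    if border_radius < 1:
        raise ConfigurationError(f"border_radius must be >= 1, got {border_radius}")
    lab = structure.labels
    w = 2 * border_radius + 1
    hi = ndimage.maximum_filter(lab, size=w, mode="nearest")
    lo = ndimage.minimum_filter(lab, size=w, mode="nearest")
    return BorderMask(mask=(hi != lo).astype(np.uint8), border_radius=border_radius)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _center_crop(px: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    H, W = size
    r0 = (px.shape[0] - H) // 2
    c0 = (px.shape[1] - W) // 2
    return px[r0 : r0 + H, c0 : c0 + W]


def assemble_mosaic(
    structure: RegionLabelMap,
    library: TextureLibrary,
    augment: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    border_radius: int = DEFAULT_BORDER_RADIUS,
    structure_type: str = "unknown",
    seed: int = -1,
) -> MosaicSample:
    """Fill each region with an independently sampled, independently augmented texture.

    Regions may reuse the same source texture (independent augmentation then
    keeps the boundary between them visible).  The target is the border band
    of the structure.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if augment is None:
        augment = AugmentConfig(enabled=False)
    H, W = structure.shape
    image = np.zeros((H, W, 3), dtype=np.float32)
    texture_ids = []
    for region in range(structure.n_regions):
        tex = sample_texture(library, rng)
        if tex.shape[0] < H or tex.shape[1] < W:
            raise InputError(
                f"texture {tex.source_id!r} is {tex.shape[0]}x{tex.shape[1]}, "
                f"smaller than the mosaic {H}x{W}"
            )
        if augment.enabled:
            tex = augment_texture(tex, augment, rng, out_size=(H, W))
            fill = tex.pixels
        else:
            fill = _center_crop(tex.pixels, (H, W))
        sel = structure.labels == region
        image[sel] = fill[sel]
        texture_ids.append(tex.source_id)
    target = border_mask(structure, border_radius)
    return MosaicSample(
        image=image,
        target=target,
        structure=structure,
        structure_type=structure_type,
        texture_ids=tuple(texture_ids),
        seed=seed,
    )


def generate_structure(
    structure_type: str, size: tuple[int, int], rng: np.random.Generator
) -> RegionLabelMap:
    """Dispatch to one structure generator, drawing its own shape parameters."""
    if structure_type == "voronoi":
        return voronoi_structure(size, int(rng.integers(2, 11)), rng)
    if structure_type == "random_walk":
        return random_walk_structure(size, rng)
    if structure_type == "circular":
        return circular_structure(size, rng)
    raise ConfigurationError(f"unknown structure type {structure_type!r}")


def generate_mosaic(
    library: TextureLibrary,
    size: tuple[int, int],
    seed: int,
    augment: AugmentConfig | None = None,
    structure_type: str | None = None,
    border_radius: int = DEFAULT_BORDER_RADIUS,
) -> MosaicSample:
    """One fully seeded mosaic sample; structure type drawn uniformly if unset."""
    rng = np.random.default_rng(seed)
    stype = structure_type or STRUCTURE_TYPES[int(rng.integers(len(STRUCTURE_TYPES)))]
    structure = generate_structure(stype, size, rng)
    return assemble_mosaic(
        structure, library, augment, rng,
        border_radius=border_radius, structure_type=stype, seed=seed,
    )


def build_dataset(
    n: int,
    library: TextureLibrary,
    out_dir: str | Path,
    rng: np.random.Generator | int = 0,
    size: tuple[int, int] = (256, 256),
    augment: AugmentConfig | None = None,
    structure_type: str | None = None,
    border_radius: int = DEFAULT_BORDER_RADIUS,
    split: str = "train",
) -> DatasetManifest:
    """Write ``n`` mosaic/mask pairs plus a JSON Lines manifest to ``out_dir``.

    For each sample a structure type is drawn uniformly (unless pinned) and a
    unique per-sample child seed is derived from the master RNG, so every
    mosaic has a different structure and the whole dataset is reproducible
    from one seed.
    """
    import imageio.v3 as iio

    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    master_seed = rng if isinstance(rng, (int, np.integer)) else -1
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    child_seeds = np.unique(rng.integers(0, 2**31 - 1, size=4 * n))[:n]
    while len(child_seeds) < n:  # astronomically unlikely
        child_seeds = np.unique(np.concatenate(
            [child_seeds, rng.integers(0, 2**31 - 1, size=4 * n)]))[:n]
    rng.shuffle(child_seeds)

    entries = []
    for i, child_seed in enumerate(child_seeds):
        sample = generate_mosaic(
            library, size, int(child_seed), augment, structure_type, border_radius
        )
        img_path = out_dir / f"mosaic_{i:06d}.png"
        mask_path = out_dir / f"mask_{i:06d}.png"
        iio.imwrite(img_path, (sample.image * 255.0 + 0.5).astype(np.uint8))
        iio.imwrite(mask_path, sample.target.mask * np.uint8(255))
        entries.append(
            {
                "image": img_path.name,
                "mask": mask_path.name,
                "structure_type": sample.structure_type,
                "seed": int(child_seed),
                "texture_ids": list(sample.texture_ids),
            }
        )
    manifest = DatasetManifest(entries=entries, split=split, seed=int(master_seed))
    manifest.save(out_dir / "manifest.jsonl")
    return manifest


def load_manifest_arrays(
    manifest: DatasetManifest, root: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    """Read all images and binarized masks of a manifest into float32 arrays."""
    import imageio.v3 as iio

    root = Path(root)
    images, masks = [], []
    for e in manifest.entries:
        img = np.asarray(iio.imread(root / e["image"]), dtype=np.float32) / 255.0
        msk = (np.asarray(iio.imread(root / e["mask"])) > 127).astype(np.float32)
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)
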