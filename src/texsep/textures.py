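"""Texture sources: procedural fixture textures and folder loaders.

Mosaic regions are filled with texture images.  Real workflows point
:func:`load_texture_folder` at a directory of photographic textures; the
procedural families in :func:`generate_procedural_texture` provide fully
self-contained, seed-deterministic stand-ins so that the whole pipeline can be
exercised without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

MIN_TEXTURE_SIZE = 32

PROCEDURAL_KINDS = ("stripes", "checkerboard", "grating", "blob_noise", "cellular")


@dataclass(frozen=True)
class TextureImage:
    """An RGB texture image with float pixels in [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Float image in [0, 1]; H, W >= 32.
    source_id : str
        Provenance tag (procedural recipe or file name).
    """

    pixels: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"texture must be HxWx3, got shape {px.shape}")
        if px.shape[0] < MIN_TEXTURE_SIZE or px.shape[1] < MIN_TEXTURE_SIZE:
            raise InputError(
                f"texture must be at least {MIN_TEXTURE_SIZE}x{MIN_TEXTURE_SIZE},"
                f" got {px.shape[0]}x{px.shape[1]}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("texture pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class TextureLibrary:
    """An ordered, non-empty collection of textures with unique source ids."""

    textures: Sequence[TextureImage]
    name: str = "library"

    def __post_init__(self) -> None:
        self.textures = list(self.textures)
        if not self.textures:
            raise InputError("texture library must be non-empty")
        ids = [t.source_id for t in self.textures]
        if len(set(ids)) != len(ids):
            raise InputError("texture source_ids must be unique")

    def __len__(self) -> int:
        return len(self.textures)

    def __getitem__(self, i: int) -> TextureImage:
        return self.textures[i]

    def __iter__(self) -> Iterator[TextureImage]:
        return iter(self.textures)


def _seeded_colors(rng: np.random.Generator, min_dist: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Two RGB colors far enough apart to keep the pattern visible."""
    a = rng.uniform(0.0, 1.0, size=3)
    while True:
        b = rng.uniform(0.0, 1.0, size=3)
        if np.abs(a - b).mean() > min_dist:
            return a.astype(np.float32), b.astype(np.float32)


def generate_procedural_texture(
    kind: str,
    size: tuple[int, int] = (64, 64),
    seed: int = 0,
    **params,
) -> TextureImage:
    """Generate a deterministic procedural texture.

    Parameters
    ----------
    kind : {"stripes", "checkerboard", "grating", "blob_noise", "cellular"}
        Procedural family.
    size : (H, W)
        Output size; both >= 32.
    seed : int
        Seeds color and noise draws; identical calls are bit-identical.
    **params
        Family-specific knobs:

        - stripes: ``period`` (int, default 8), ``angle`` (deg, default 0)
        - checkerboard: ``cell`` (int, default 8)
        - grating: ``period`` (float, default 12), ``angle`` (deg, default 30)
        - blob_noise: ``sigma`` (float, default 3)
        - cellular: ``n_points`` (int, default 12)
    """
    H, W = size
    if H < MIN_TEXTURE_SIZE or W < MIN_TEXTURE_SIZE:
        raise ConfigurationError(f"size must be >= {MIN_TEXTURE_SIZE}, got {size}")
    if kind not in PROCEDURAL_KINDS:
        raise ConfigurationError(
            f"unknown procedural kind {kind!r}; choose from {PROCEDURAL_KINDS}"
        )
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float32)

    if kind == "stripes":
        period = int(params.pop("period", 8))
        angle = float(params.pop("angle", 0.0))
        ca, cb = _seeded_colors(rng)
        theta = np.deg2rad(angle)
        # coordinate along the stripe normal; angle 0 -> varies with column only
        u = cols * np.cos(theta) + rows * np.sin(theta)
        phase = np.floor(u).astype(np.int64) % period
        on = phase < period // 2
        img = np.where(on[..., None], ca, cb)
    elif kind == "checkerboard":
        cell = int(params.pop("cell", 8))
        ca, cb = _seeded_colors(rng)
        on = ((rows.astype(np.int64) // cell) + (cols.astype(np.int64) // cell)) % 2 == 0
        img = np.where(on[..., None], ca, cb)
    elif kind == "grating":
        period = float(params.pop("period", 12.0))
        angle = float(params.pop("angle", 30.0))
        ca, cb = _seeded_colors(rng)
        theta = np.deg2rad(angle)
        u = cols * np.cos(theta) + rows * np.sin(theta)
        w = 0.5 * (1.0 + np.sin(2.0 * np.pi * u / period))
        img = w[..., None] * ca + (1.0 - w[..., None]) * cb
    elif kind == "blob_noise":
        from scipy.ndimage import gaussian_filter

        sigma = float(params.pop("sigma", 3.0))
        noise = rng.uniform(0.0, 1.0, size=(H, W, 3))
        img = gaussian_filter(noise, sigma=(sigma, sigma, 0), mode="wrap")
        # smoothing shrinks the dynamic range; stretch per channel around the mean
        lo = img.min(axis=(0, 1), keepdims=True)
        hi = img.max(axis=(0, 1), keepdims=True)
        img = (img - lo) / np.maximum(hi - lo, 1e-8)
    else:  # cellular
        n_points = int(params.pop("n_points", 12))
        pts = rng.uniform(0.0, 1.0, size=(n_points, 2)) * np.array([H, W])
        d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
        d = np.sqrt(d2.min(axis=-1))
        d = d / max(d.max(), 1e-8)
        tint = rng.uniform(0.3, 1.0, size=3)
        img = d[..., None] * tint + (1.0 - d[..., None]) * (1.0 - tint)

    if params:
        raise ConfigurationError(f"unknown parameters for kind {kind!r}: {sorted(params)}")
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    tag = f"procedural:{kind}:{H}x{W}:seed={seed}"
    return TextureImage(pixels=img, source_id=tag)


def default_procedural_library(
    size: tuple[int, int] = (96, 96), seed: int = 0, kinds: Sequence[str] = PROCEDURAL_KINDS
) -> TextureLibrary:
    """One texture of each requested kind, seeded from ``seed``."""
    textures = [
        generate_procedural_texture(kind, size=size, seed=seed + i)
        for i, kind in enumerate(kinds)
    ]
    return TextureLibrary(textures=textures, name="procedural")


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def _decode_to_unit_rgb(raw: np.ndarray) -> np.ndarray:
    """Scale an 8/16-bit or float image to [0,1] RGB (replicating grayscale)."""
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    else:
        arr = np.clip(arr.astype(np.float32), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    return arr


def load_texture_folder(path: str | Path, name: str | None = None) -> TextureLibrary:
    """Load every PNG/TIFF in ``path`` (lexicographic order) as a texture library.

    Grayscale images are replicated to 3 channels; 16-bit images are scaled by
    65535.  Undecodable files are skipped with a warning; an empty or
    all-undecodable folder raises :class:`InputError`.
    """
    import imageio.v3 as iio

    folder = Path(path)
    if not folder.is_dir():
        raise InputError(f"not a directory: {folder}")
    files = sorted(p for p in folder.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    textures: list[TextureImage] = []
    for f in files:
        try:
            raw = iio.imread(f)
        except Exception as exc:  # undecodable file: skip, keep going
            logger.warning("skipping undecodable image %s: %s", f.name, exc)
            continue
        textures.append(TextureImage(pixels=_decode_to_unit_rgb(raw), source_id=f.name))
    if not textures:
        raise InputError(f"no readable PNG/TIFF images in {folder}")
    return TextureLibrary(textures=textures, name=name or folder.name)


def sample_texture(library: TextureLibrary, rng: np.random.Generator) -> TextureImage:
    """Draw one texture uniformly at random from the library."""
    return library[int(rng.integers(len(library)))]
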