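"""Per-texture augmentation: random affine warp, uniform noise, one photometric op.

Each mosaic region is filled with an independently augmented texture, which
decorrelates regions that happen to reuse the same source texture and exposes
the classifier to rotation, scale, shear, noise and tone variation.  All
random parameters are drawn from uniform distributions over configurable
intervals; the defaults are

====================  ==============  ==============
procedure             inferior limit  superior limit
====================  ==============  ==============
rotation              0 deg           360 deg
translation           -12 px          +12 px
scale change          0.5x            1.5x
shear                 -30 deg         +30 deg
uniform noise         0               0.02
Gaussian blur sigma   0               5
gamma                 0.5             1.5
====================  ==============  ==============

The photometric stage applies exactly one operation drawn uniformly from a
seven-item menu: adaptive histogram equalization, histogram equalization,
logarithmic adjustment, sigmoid adjustment, gamma correction, Gaussian
blurring, or inversion (the equalization/log/sigmoid operations use
scikit-image defaults: CLAHE defaults, log gain 1, sigmoid cutoff 0.5 /
gain 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, filters, transform

from .errors import ConfigurationError, InputError
from .textures import TextureImage

PHOTOMETRIC_MENU = (
    "adaptive_equalize",
    "equalize",
    "log",
    "sigmoid",
    "gamma",
    "blur",
    "invert",
)

Interval = tuple[float, float]


@dataclass
class AugmentConfig:
    """Intervals of the uniform draws for every augmentation parameter.

    Degenerate intervals (lo == hi) pin a parameter, which is how tests force
    identity transforms; when ``enabled`` is False the whole chain is a no-op.
    """

    enabled: bool = True
    rotation_deg: Interval = (0.0, 360.0)
    translation_px: Interval = (-12.0, 12.0)
    scale: Interval = (0.5, 1.5)
    shear_deg: Interval = (-30.0, 30.0)
    noise_amplitude: Interval = (0.0, 0.02)
    gaussian_sigma: Interval = (0.0, 5.0)
    gamma: Interval = (0.5, 1.5)
    photometric_menu: tuple[str, ...] = PHOTOMETRIC_MENU

    def __post_init__(self) -> None:
        for name in (
            "rotation_deg",
            "translation_px",
            "scale",
            "shear_deg",
            "noise_amplitude",
            "gaussian_sigma",
            "gamma",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name}: interval [{lo}, {hi}] is inverted")
        self.photometric_menu = tuple(self.photometric_menu)
        unknown = set(self.photometric_menu) - set(PHOTOMETRIC_MENU)
        if unknown:
            raise ConfigurationError(f"unknown photometric operations: {sorted(unknown)}")


def _draw(rng: np.random.Generator, interval: Interval) -> float:
    lo, hi = interval
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def geometric_augment(
    image: TextureImage,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    out_size: tuple[int, int] | None = None,
) -> TextureImage:
    """Random rotation, translation, shear and scale, then central crop.

    The four draws are composed into a single affine map about the image
    center (rotation * shear * scale, then translation) and applied once with
    bilinear interpolation and reflective padding, so no out-of-support pixels
    appear in the crop.
    """
    H, W = image.shape
    oh, ow = out_size if out_size is not None else (H, W)
    if oh > H or ow > W:
        raise InputError(
            f"crop {oh}x{ow} exceeds source texture {H}x{W}; use a larger texture"
        )
    angle = np.deg2rad(_draw(rng, cfg.rotation_deg))
    tx = _draw(rng, cfg.translation_px)
    ty = _draw(rng, cfg.translation_px)
    s = _draw(rng, cfg.scale)
    shear = np.deg2rad(_draw(rng, cfg.shear_deg))

    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    tf = (
        transform.AffineTransform(translation=-center)
        + transform.AffineTransform(rotation=angle, shear=shear, scale=(s, s))
        + transform.AffineTransform(translation=center + np.array([tx, ty]))
    )
    warped = transform.warp(
        image.pixels, tf.inverse, order=1, mode="reflect", preserve_range=True
    )
    r0 = (H - oh) // 2
    c0 = (W - ow) // 2
    out = np.clip(warped[r0 : r0 + oh, c0 : c0 + ow], 0.0, 1.0).astype(np.float32)
    return TextureImage(pixels=out, source_id=image.source_id)


def add_uniform_noise(
    image: TextureImage, cfg: AugmentConfig, rng: np.random.Generator
) -> TextureImage:
    """Additive per-pixel noise U[-A, A]; amplitude A itself is drawn uniformly."""
    amplitude = _draw(rng, cfg.noise_amplitude)
    if amplitude == 0.0:
        return image
    noise = rng.uniform(-amplitude, amplitude, size=image.pixels.shape)
    out = np.clip(image.pixels + noise, 0.0, 1.0).astype(np.float32)
    return TextureImage(pixels=out, source_id=image.source_id)


def _op_adaptive_equalize(px, cfg, rng):
    return exposure.equalize_adapthist(px)


def _op_equalize(px, cfg, rng):
    return exposure.equalize_hist(px)


def _op_log(px, cfg, rng):
    return exposure.adjust_log(px, gain=1)


def _op_sigmoid(px, cfg, rng):
    return exposure.adjust_sigmoid(px, cutoff=0.5, gain=10)


def _op_gamma(px, cfg, rng):
    return exposure.adjust_gamma(px, gamma=_draw(rng, cfg.gamma))


def _op_blur(px, cfg, rng):
    sigma = _draw(rng, cfg.gaussian_sigma)
    if sigma == 0.0:
        return px
    return filters.gaussian(px, sigma=sigma, channel_axis=-1)


def _op_invert(px, cfg, rng):
    return 1.0 - px


PHOTOMETRIC_OPS = {
    "adaptive_equalize": _op_adaptive_equalize,
    "equalize": _op_equalize,
    "log": _op_log,
    "sigmoid": _op_sigmoid,
    "gamma": _op_gamma,
    "blur": _op_blur,
    "invert": _op_invert,
}


def random_photometric(
    image: TextureImage,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    op: str | None = None,
) -> TextureImage:
    """Apply exactly one photometric operation, drawn uniformly from the menu.

    ``op`` pins the choice (used by tests and by callers that restrict the
    menu to a single operation).
    """
    if op is None:
        if not cfg.photometric_menu:
            raise ConfigurationError("photometric_menu is empty; nothing to draw")
        op = cfg.photometric_menu[int(rng.integers(len(cfg.photometric_menu)))]
    if op not in PHOTOMETRIC_OPS:
        raise ConfigurationError(f"unknown photometric operation {op!r}")
    out = PHOTOMETRIC_OPS[op](image.pixels, cfg, rng)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    return TextureImage(pixels=out, source_id=image.source_id)


def augment_texture(
    image: TextureImage,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    out_size: tuple[int, int] | None = None,
) -> TextureImage:
    """Full chain: geometric warp -> uniform noise -> one photometric op.

    With ``cfg.enabled`` False the input is returned unchanged (no crop); an
    empty ``photometric_menu`` skips the photometric stage only.
    """
    if not cfg.enabled:
        return image
    out = geometric_augment(image, cfg, rng, out_size=out_size)
    out = add_uniform_noise(out, cfg, rng)
    if cfg.photometric_menu:
        out = random_photometric(out, cfg, rng)
    return out
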