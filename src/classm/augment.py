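"""Two-stage augmentation: color jitter on RGB tiles before stain
separation, then independent geometric/brightness augmentation of the
separated H and E channel images.

The H stream and E stream of one sample consume independent random draws,
so e.g. their rotation angles differ.  An identity configuration is an
exact no-op (factor-1 jitters are skipped rather than applied in floating
point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stainsep import RGBTile

__all__ = ["AugmentConfig", "jitter_rgb", "augment_channel", "center_crop"]


def _check_range(name: str, rng_pair: tuple[float, float]) -> None:
    lo, hi = rng_pair
    if not (0 < lo <= 1.0 <= hi):
        raise ValueError(
            f"{name} range {rng_pair} must be a closed interval containing 1 "
            "with positive lower bound"
        )


@dataclass(frozen=True)
class AugmentConfig:
    """All augmentation knobs; every range is a closed interval containing 1."""

    rgb_brightness: tuple[float, float] = (0.9, 1.1)
    rgb_contrast: tuple[float, float] = (0.9, 1.1)
    rgb_saturation: tuple[float, float] = (0.9, 1.1)
    crop_size: int = 64
    rotation_degrees: float = 180.0  # max |angle|; 0 disables rotation
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    channel_brightness: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        _check_range("rgb_brightness", self.rgb_brightness)
        _check_range("rgb_contrast", self.rgb_contrast)
        _check_range("rgb_saturation", self.rgb_saturation)
        _check_range("channel_brightness", self.channel_brightness)
        if self.crop_size < 0:
            raise ValueError("crop_size must be >= 0 (0 = no crop)")
        if self.rotation_degrees < 0:
            raise ValueError("rotation_degrees must be >= 0")
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")

    @classmethod
    def identity(cls, crop_size: int = 0) -> "AugmentConfig":
        """A configuration under which both stages are exact no-ops
        (``crop_size`` 0 means crop to the full image)."""
        return cls(
            rgb_brightness=(1.0, 1.0),
            rgb_contrast=(1.0, 1.0),
            rgb_saturation=(1.0, 1.0),
            crop_size=crop_size,
            rotation_degrees=0.0,
            hflip_prob=0.0,
            vflip_prob=0.0,
            channel_brightness=(1.0, 1.0),
        )


def jitter_rgb(tile: RGBTile, config: AugmentConfig,
               rng: np.random.Generator) -> RGBTile:
    """Color jitter (brightness, contrast, saturation) of an RGB tile."""
    b = rng.uniform(*config.rgb_brightness)
    c = rng.uniform(*config.rgb_contrast)
    s = rng.uniform(*config.rgb_saturation)
    x = np.asarray(tile.pixels, dtype=float)
    gray_weights = np.array([0.299, 0.587, 0.114])
    if b != 1.0:
        x = x * b
    if c != 1.0:
        mean = float((x @ gray_weights).mean())
        x = mean + c * (x - mean)
    if s != 1.0:
        gray = x @ gray_weights
        x = gray[..., None] + s * (x - gray[..., None])
    x = np.clip(np.rint(x), 0, tile.background_intensity).astype(np.int64)
    return RGBTile(x, tile.background_intensity, tile.slide_id)


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    size = min(size, h, w)
    top = (h - size) // 2
    left = (w - size) // 2
    return image[top : top + size, left : left + size]


def augment_channel(image: np.ndarray, config: AugmentConfig,
                    rng: np.random.Generator,
                    crop_size: int | None = None) -> np.ndarray:
    """Geometric + brightness augmentation of one channel image in [0, 1].

    Order: continuous-angle rotation with reflection padding, random crop,
    random horizontal/vertical flip, multiplicative brightness jitter, clip.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    size = crop_size if crop_size is not None else config.crop_size
    if size == 0:
        size = min(h, w)
    if size > min(h, w):
        raise ValueError(f"crop {size} larger than image {image.shape}")

    out = image
    if config.rotation_degrees > 0:
        angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
        out = ndimage.rotate(out, angle, reshape=False, mode="reflect",
                             order=1)
    if (h, w) != (size, size):
        top = int(rng.integers(0, h - size + 1))
        left = int(rng.integers(0, w - size + 1))
        out = out[top : top + size, left : left + size]
    if config.hflip_prob > 0 and rng.random() < config.hflip_prob:
        out = out[:, ::-1]
    if config.vflip_prob > 0 and rng.random() < config.vflip_prob:
        out = out[::-1, :]
    lo, hi = config.channel_brightness
    if (lo, hi) != (1.0, 1.0):
        out = out * rng.uniform(lo, hi)
    return np.clip(out, 0.0, 1.0) if out is not image else image.copy()
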