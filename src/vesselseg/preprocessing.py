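"""Contrast-enhancement preprocessing for fundus images.

Fundus photographs show vessels with the best vessel/background contrast in
the green channel.  The pipeline builds a pseudo-colour image from three
derived channels and collapses it to one enhanced grayscale plane:

1. extract the green channel;
2. CLAHE (contrast-limited adaptive histogram equalization) of the green
   channel;
3. gamma transform of the green channel;
4. stack the three channels;
5. convert the stack to grayscale and rescale to [0, 1].

The stacked channels are not R/G/B semantically, so the grayscale
conversion defaults to equal weights (configurable, e.g. to luminance
weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "FundusImage",
    "EnhancedImage",
    "PreprocessConfig",
    "extract_green",
    "apply_clahe",
    "apply_gamma",
    "preprocess",
]


@dataclass
class FundusImage:
    """An RGB fundus photograph with an optional circular field-of-view mask.

    ``pixels`` is (H, W, 3) with values in [0, 255]; ``fov_mask`` is a
    binary (H, W) array or None; ``source_id`` is a free-form label.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"expected (H, W, 3) RGB array, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise InvalidInputError("pixel values must lie in [0, 255]")
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask)
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise InvalidInputError(
                    f"fov_mask shape {self.fov_mask.shape} does not match "
                    f"image shape {self.pixels.shape[:2]}")


@dataclass
class EnhancedImage:
    """Single-channel enhanced image, values in [0, 1], same H x W as source."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InvalidInputError("EnhancedImage must be single-channel (H, W)")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise InvalidInputError("EnhancedImage values must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)


@dataclass
class PreprocessConfig:
    """Knobs of the enhancement pipeline.

    clip_limit and tile_grid parametrize CLAHE; gamma > 1 darkens mid-tones
    of the green channel (gamma < 1 brightens — both readings of the
    gamma step are reachable through this single signed knob).
    gray_weights are the channel weights of the final grayscale conversion.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    gray_weights: tuple[float, float, float] = field(
        default=(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0))


def extract_green(img: FundusImage) -> np.ndarray:
    """Return the green channel of ``img`` unchanged, values in [0, 255]."""
    px = np.asarray(img.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InvalidInputError("extract_green requires a 3-channel image")
    return np.asarray(px[:, :, 1], dtype=np.float64)


def apply_clahe(channel: np.ndarray, clip_limit: float = 2.0,
                tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one channel.

    Input and output are in [0, 255].  ``clip_limit`` follows the common
    absolute convention (typical values 1-4) and is mapped to
    scikit-image's normalized clip limit; ``tile_grid`` is the number of
    contextual tiles (rows, cols).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise InvalidInputError("apply_clahe expects a single-channel array")
    h, w = channel.shape
    ty, tx = int(tile_grid[0]), int(tile_grid[1])
    if ty < 1 or tx < 1:
        raise InvalidConfigError("tile_grid entries must be >= 1")
    if ty > h or tx > w:
        raise InvalidConfigError(
            f"tile grid {tile_grid} larger than image {channel.shape}")
    if channel.max() == channel.min():
        return channel.copy()  # constant image: nothing to equalize
    out = exposure.equalize_adapthist(
        channel / 255.0,
        kernel_size=(max(1, h // ty), max(1, w // tx)),
        clip_limit=min(1.0, clip_limit / 100.0),
    )
    return out * 255.0


def apply_gamma(channel: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power transform ``channel ** gamma`` on a [0, 1] channel."""
    if gamma <= 0:
        raise InvalidConfigError(f"gamma must be > 0, got {gamma}")
    channel = np.asarray(channel, dtype=np.float64)
    return np.power(channel, gamma)


def preprocess(img: FundusImage, cfg: PreprocessConfig | None = None) -> EnhancedImage:
    """Run the full five-step enhancement, returning a [0, 1] grayscale image."""
    cfg = cfg or PreprocessConfig()
    green = extract_green(img)                                   # [0,255]
    clahe = apply_clahe(green, cfg.clip_limit, cfg.tile_grid)    # [0,255]
    gamma = apply_gamma(green / 255.0, cfg.gamma) * 255.0        # [0,255]
    stack = np.stack([green, clahe, gamma], axis=-1)
    w = np.asarray(cfg.gray_weights, dtype=np.float64)
    if w.shape != (3,) or w.sum() <= 0:
        raise InvalidConfigError("gray_weights must be 3 non-negative values")
    gray = stack @ (w / w.sum())
    gray = np.clip(gray / 255.0, 0.0, 1.0)
    return EnhancedImage(pixels=gray, source_id=img.source_id)
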