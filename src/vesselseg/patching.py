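"""Patch sampling for training and sliding-window extraction for inference.

Training draws fixed-size patches at random positions whose window lies
fully inside the image, cutting the label map at identical coordinates.
Test-time inference slides a window (default 128 px, stride 5 px) across
the image in row-major order; windows may overhang the right/bottom border,
in which case the missing part is zero-filled on extraction and discarded
on reassembly.  Overlapping predictions are recomposed by per-pixel
arithmetic mean.

Coordinates are 0-based (column, row) with half-open windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PatchGrid",
    "make_patch_grid",
    "extract_patches",
    "sample_training_patches",
    "reassemble",
]


@dataclass(frozen=True)
class PatchGrid:
    """Sliding-window layout over an image.

    ``origins`` lists (col, row) top-left corners in row-major order;
    ``image_dims`` is (width, height).
    """

    window: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    image_dims: tuple[int, int]


def _axis_origins(extent: int, window: int, stride: int) -> list[int]:
    """Origins 0, stride, ... up to the first window that reaches the border."""
    if extent <= window:
        return [0]
    out = []
    pos = 0
    while True:
        out.append(pos)
        if pos + window >= extent:
            break
        pos += stride
    return out


def make_patch_grid(image_dims: tuple[int, int], window: int = 128,
                    stride: int = 5) -> PatchGrid:
    """Row-major sliding-window grid covering every pixel of the image.

    ``image_dims`` is (width, height).  The last window per axis may
    overhang the image; the number of origins per axis is
    ceil((extent - window) / stride) + 1 for extent > window, else 1.
    """
    if window < 1 or stride < 1:
        raise InvalidInputError("window and stride must be >= 1")
    w, h = int(image_dims[0]), int(image_dims[1])
    cols = _axis_origins(w, window, stride)
    rows = _axis_origins(h, window, stride)
    origins = tuple((c, r) for r in rows for c in cols)
    return PatchGrid(window=window, stride=stride, origins=origins,
                     image_dims=(w, h))


def extract_patches(img: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Cut every grid window from an (H, W) image, zero-filling overhang.

    Returns an array (n_patches, window, window).
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if (w, h) != grid.image_dims:
        raise InvalidInputError(
            f"image dims {(w, h)} do not match grid {grid.image_dims}")
    k = grid.window
    out = np.zeros((len(grid.origins), k, k), dtype=np.float64)
    for i, (c, r) in enumerate(grid.origins):
        ch, cw = min(k, h - r), min(k, w - c)
        out[i, :ch, :cw] = img[r:r + ch, c:c + cw]
    return out


def sample_training_patches(img: np.ndarray, label: np.ndarray, n: int,
                            size: int = 128, seed: int | None = 0,
                            fov: np.ndarray | None = None,
                            min_fov_fraction: float = 0.5):
    """Randomly cut ``n`` aligned (image, label) patch pairs.

    Origins are uniform over positions whose window lies fully inside the
    image.  If ``fov`` is given, candidate windows must have at least
    ``min_fov_fraction`` of their area inside the field of view, avoiding
    all-background border patches.  Deterministic for a fixed seed.
    """
    img = np.asarray(img, dtype=np.float64)
    label = np.asarray(label)
    if img.shape != label.shape:
        raise InvalidInputError(
            f"image {img.shape} and label {label.shape} shapes differ")
    h, w = img.shape
    if h < size or w < size:
        raise InvalidInputError(
            f"image {img.shape} smaller than patch size {size}")
    rng = np.random.default_rng(seed)
    pairs = []
    if fov is not None:
        # cumulative-sum area table for O(1) in-FOV fraction per window
        ii = np.pad(np.cumsum(np.cumsum(np.asarray(fov, dtype=np.float64),
                                        axis=0), axis=1), ((1, 0), (1, 0)))
    tries = 0
    while len(pairs) < n:
        r = int(rng.integers(0, h - size + 1))
        c = int(rng.integers(0, w - size + 1))
        if fov is not None:
            area = (ii[r + size, c + size] - ii[r, c + size]
                    - ii[r + size, c] + ii[r, c])
            tries += 1
            if area < min_fov_fraction * size * size and tries < 100 * n:
                continue
        pairs.append((img[r:r + size, c:c + size].copy(),
                      label[r:r + size, c:c + size].copy()))
    return pairs


def reassemble(prob_patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Average overlapping probability patches back into a full-size map.

    Overhanging parts of border windows are discarded.  Every in-image
    pixel is covered by at least one window by grid construction.
    """
    prob_patches = np.asarray(prob_patches, dtype=np.float64)
    if len(prob_patches) != len(grid.origins):
        raise InvalidInputError(
            f"{len(prob_patches)} patches for {len(grid.origins)} grid origins")
    w, h = grid.image_dims
    k = grid.window
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    for patch, (c, r) in zip(prob_patches, grid.origins):
        ch, cw = min(k, h - r), min(k, w - c)
        acc[r:r + ch, c:c + cw] += patch[:ch, :cw]
        cnt[r:r + ch, c:c + cw] += 1.0
    return acc / cnt
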