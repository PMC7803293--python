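"""Image readers and writers (PNG/TIFF/JPEG/GIF via imageio)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "write_probability_png"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as a NumPy array; GIF frames are squeezed to 2-D/3-D."""
    arr = np.asarray(iio.imread(path))
    # animated-GIF style (frames, H, W[, C]) with one frame
    if arr.ndim in (3, 4) and arr.shape[0] == 1 and arr.shape[-1] not in (3, 4):
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[2] == 4:       # drop alpha
        arr = arr[:, :, :3]
    return arr


def write_image(path: str | Path, arr: np.ndarray) -> None:
    """Write an 8-bit image (grayscale or RGB)."""
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_probability_png(path: str | Path, prob: np.ndarray) -> None:
    """Write a [0, 1] probability map as a 16-bit grayscale PNG."""
    prob = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(prob * 65535.0).astype(np.uint16))
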