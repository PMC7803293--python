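"""End-to-end helpers chaining preprocessing, inference and postprocessing."""

from __future__ import annotations

import numpy as np

from .model import BFCN
from .patching import extract_patches, make_patch_grid, reassemble
from .postprocessing import binarize, sharpen
from .preprocessing import EnhancedImage, FundusImage, PreprocessConfig, preprocess

__all__ = ["predict_image", "segment"]


def predict_image(model: BFCN, enhanced: EnhancedImage | np.ndarray,
                  window: int = 128, stride: int = 5,
                  batch: int = 16) -> np.ndarray:
    """Sliding-window inference: full-image vessel probability map.

    Extracts ``window``-sized patches at the given stride (overhang
    zero-filled), runs them through the model in batches, and averages
    overlapping predictions back to image size.
    """
    img = enhanced.pixels if isinstance(enhanced, EnhancedImage) else np.asarray(enhanced)
    h, w = img.shape
    grid = make_patch_grid((w, h), window=window, stride=stride)
    patches = extract_patches(img, grid)
    probs = np.empty_like(patches)
    for start in range(0, len(patches), batch):
        probs[start:start + batch] = model.predict(patches[start:start + batch])
    return reassemble(probs, grid)


def segment(model: BFCN, img: FundusImage,
            pre_cfg: PreprocessConfig | None = None,
            window: int = 128, stride: int = 5,
            sharpen_mode: str = "abs_template",
            threshold: float = 0.5):
    """Full pipeline: enhance, predict, sharpen, threshold.

    Returns ``(mask, prob_sharp, prob_raw)``.
    """
    enhanced = preprocess(img, pre_cfg)
    prob = predict_image(model, enhanced, window=window, stride=stride)
    prob_sharp = sharpen(prob, mode=sharpen_mode)
    mask = binarize(prob_sharp, threshold)
    return mask, prob_sharp, prob
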