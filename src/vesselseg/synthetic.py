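"""Synthetic vascular phantoms with paired ground truth.

The generator emulates the properties of fundus photographs that matter to
the segmentation pipeline: a circular field of view, branching tubular
vessels of varying width (1-8 px) rendered dark against a brighter
background, strongest vessel/background contrast in the green channel, a
smooth illumination gradient, and additive Gaussian noise.  Vessel trees
are grown from the FOV boundary inward by biased random walks; each
segment is stamped with a truncated Gaussian cross-profile, so the ground
truth (the profile's support) is pixel-aligned with the rendered vessel by
construction.

Optionally, short runs of segments are deleted from the rendered image
(but kept in the ground truth and recorded in a break mask) to create the
small-vessel gaps that the sharpening postprocessing is meant to bridge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError
from .io import read_image, write_image
from .preprocessing import FundusImage

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_dataset",
           "read_dataset"]


@dataclass
class PhantomSpec:
    """Parameters of one phantom image.

    dims:               (width, height) in pixels.
    n_trees:            number of vessel trees grown from the FOV border.
    width_range:        trunk width bounds in pixels (within [1, 8]).
    contrast:           vessel/background intensity gap in the green
                        channel, in (0, 1].
    illumination_slope: amplitude of the linear background ramp.
    noise_sd:           sigma of additive Gaussian noise.
    break_rate:         per-step probability of starting a short rendered
                        gap (ground truth unaffected).
    seed:               generator seed; fixed seed gives a bit-identical
                        phantom.
    """

    dims: tuple[int, int] = (256, 256)
    n_trees: int = 6
    width_range: tuple[float, float] = (1.0, 8.0)
    contrast: float = 0.35
    illumination_slope: float = 0.15
    noise_sd: float = 0.05
    break_rate: float = 0.0
    seed: int = 0
    base_intensity: float = 0.55

    def __post_init__(self):
        lo, hi = self.width_range
        if not (1.0 <= lo <= hi <= 8.0):
            raise InvalidConfigError(
                f"width_range must lie within [1, 8], got {self.width_range}")
        if not (0.0 < self.contrast <= 1.0):
            raise InvalidConfigError(
                f"contrast must be in (0, 1], got {self.contrast}")


@dataclass
class Phantom:
    """A generated phantom: RGB image, ground truth, FOV, break bookkeeping.

    ``vesselness`` is the noiseless, normalized ([0, 1]) vessel profile
    whose support equals ``truth`` exactly; ``breaks`` marks truth pixels
    whose rendering was suppressed by ``break_rate``.
    """

    image: FundusImage
    truth: np.ndarray
    fov: np.ndarray
    breaks: np.ndarray
    vesselness: np.ndarray


def _stamp(canvas_v, canvas_t, cx, cy, radius, suppressed, breaks):
    """Stamp one truncated-Gaussian vessel cross-section disc."""
    h, w = canvas_v.shape
    r_int = int(np.ceil(radius))
    x0, x1 = max(0, int(cx) - r_int - 1), min(w, int(cx) + r_int + 2)
    y0, y1 = max(0, int(cy) - r_int - 1), min(h, int(cy) + r_int + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    inside = d2 <= radius * radius
    if not inside.any():
        # sub-pixel vessel: keep at least the nearest pixel
        iy, ix = np.unravel_index(np.argmin(d2), d2.shape)
        inside[iy, ix] = True
    sigma = max(radius / 1.5, 0.5)
    profile = np.where(inside, np.exp(-d2 / (2.0 * sigma * sigma)), 0.0)
    canvas_t[y0:y1, x0:x1] |= inside
    if suppressed:
        breaks[y0:y1, x0:x1] |= inside
    else:
        np.maximum(canvas_v[y0:y1, x0:x1], profile, out=canvas_v[y0:y1, x0:x1])


def _grow_tree(rng, spec, vessel, truth, breaks, cx0, cy0, theta, width,
               max_steps=140):
    """Biased random walk rendering one vessel (recursing into branches)."""
    w, h = spec.dims
    ccx, ccy = w / 2.0, h / 2.0
    radius_fov = min(w, h) / 2.0 - 2.0
    x, y = cx0, cy0
    suppressed_left = 0
    for step in range(max_steps):
        if width < 0.9:
            break
        if (x - ccx) ** 2 + (y - ccy) ** 2 > radius_fov ** 2:
            break
        if suppressed_left == 0 and spec.break_rate > 0 \
                and rng.random() < spec.break_rate:
            suppressed_left = int(rng.integers(2, 5))
        _stamp(vessel, truth, x, y, width / 2.0, suppressed_left > 0, breaks)
        if suppressed_left > 0:
            suppressed_left -= 1
        # direction jitter plus a weak centripetal pull
        to_c = np.arctan2(ccy - y, ccx - x)
        dtheta = rng.normal(0.0, 0.25)
        pull = 0.06 * np.sin(to_c - theta)
        theta = theta + dtheta + pull
        x += 1.8 * np.cos(theta)
        y += 1.8 * np.sin(theta)
        width *= 0.985
        if width > 1.4 and rng.random() < 0.035:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            _grow_tree(rng, spec, vessel, truth, breaks, x, y,
                       theta + sign * rng.uniform(0.5, 1.0),
                       width * rng.uniform(0.55, 0.8),
                       max_steps=max_steps // 2)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom (image, ground truth, FOV) from a seeded spec."""
    w, h = spec.dims
    rng = np.random.default_rng(spec.seed)
    vessel = np.zeros((h, w), dtype=np.float64)
    truth = np.zeros((h, w), dtype=bool)
    breaks = np.zeros((h, w), dtype=bool)

    ccx, ccy = w / 2.0, h / 2.0
    radius_fov = min(w, h) / 2.0 - 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    fov = ((xx - ccx) ** 2 + (yy - ccy) ** 2) <= radius_fov ** 2

    lo, hi = spec.width_range
    for _ in range(spec.n_trees):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x0 = ccx + (radius_fov - 1.0) * np.cos(phi)
        y0 = ccy + (radius_fov - 1.0) * np.sin(phi)
        theta = phi + np.pi + rng.normal(0.0, 0.3)   # inward
        width = rng.uniform(max(lo, 0.5 * hi), hi)
        _grow_tree(rng, spec, vessel, truth, breaks, x0, y0, theta, width)

    truth &= fov
    breaks &= fov
    vessel *= fov

    # background: base + linear illumination ramp
    ang = rng.uniform(0.0, 2.0 * np.pi)
    ramp = ((xx * np.cos(ang) + yy * np.sin(ang)) / np.hypot(w, h))
    ramp = (ramp - ramp.mean()) * 2.0 * spec.illumination_slope
    base = spec.base_intensity + ramp

    def channel(level, vessel_contrast):
        ch = np.clip(level - vessel_contrast * vessel, 0.0, 1.0)
        ch += rng.normal(0.0, spec.noise_sd, ch.shape)
        ch = np.where(fov, ch, 0.02)
        return np.clip(ch, 0.0, 1.0)

    green = channel(base, spec.contrast)
    red = channel(np.clip(base + 0.2, 0.0, 1.0), 0.3 * spec.contrast)
    blue = channel(np.clip(base - 0.3, 0.0, 1.0), 0.15 * spec.contrast)
    rgb = np.round(np.stack([red, green, blue], axis=-1) * 255.0)

    img = FundusImage(pixels=rgb, fov_mask=fov.astype(np.uint8),
                      source_id=f"phantom-{spec.seed}")
    return Phantom(image=img, truth=truth.astype(np.uint8),
                   fov=fov.astype(np.uint8), breaks=breaks.astype(np.uint8),
                   vesselness=vessel)


def generate_dataset(spec: PhantomSpec, n_images: int, out_dir: str | Path):
    """Write ``n_images`` phantoms in a DRIVE-style layout.

    Creates ``images/``, ``labels/`` and ``masks/`` with paired PNG
    filenames plus a ``manifest.json`` recording the spec and per-image
    seeds.  Returns the list of written image paths.
    """
    out = Path(out_dir)
    for sub in ("images", "labels", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    written = []
    seeds = []
    for i in range(n_images):
        sub_spec = PhantomSpec(**{**asdict(spec), "seed": spec.seed + i})
        ph = generate_phantom(sub_spec)
        stem = f"{i + 1:02d}"
        write_image(out / "images" / f"{stem}.png",
                    ph.image.pixels.astype(np.uint8))
        write_image(out / "labels" / f"{stem}.png", ph.truth * 255)
        write_image(out / "masks" / f"{stem}.png", ph.fov * 255)
        written.append(out / "images" / f"{stem}.png")
        seeds.append(sub_spec.seed)
    manifest = {**asdict(spec), "n_images": n_images, "seeds": seeds}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return written


def read_dataset(data_dir: str | Path):
    """Load a DRIVE-style directory back into (FundusImage, truth, fov) triples."""
    data_dir = Path(data_dir)
    triples = []
    for img_path in sorted((data_dir / "images").iterdir()):
        stem = img_path.name
        rgb = read_image(img_path)
        truth = (read_image(data_dir / "labels" / stem) > 127).astype(np.uint8)
        fov = (read_image(data_dir / "masks" / stem) > 127).astype(np.uint8)
        triples.append((FundusImage(pixels=rgb, fov_mask=fov,
                                    source_id=img_path.stem), truth, fov))
    return triples
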