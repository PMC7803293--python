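"""Butterfly fully-convolutional network (BFCN) for vessel segmentation.

The network is a U-shaped encoder-decoder specialised for thin, low-contrast
tubular structures:

* **Multiscale information extraction (MSIE) blocks** in the encoder run four
  parallel dilated 3x3 convolutions with distinct expansion rates next to a
  1x1 branch that keeps the current scale, widening the receptive field
  without extra kernel weights, then fuse the branches and recalibrate
  channels with a squeeze-and-excite style gate.
* **Transfer layers** gate each skip connection: a channel gate alpha is
  derived from spatially max/mean-pooled descriptors, then a spatial gate
  beta from per-pixel channel max/mean maps, suppressing uninformative
  encoder features before they reach the decoder.
* **Side inputs** feed a downscaled copy of the input image into every
  encoder level, building an image pyramid.
* The **decoder** upsamples by 2 per level with transposed convolutions,
  concatenates the gated skip, and refines with two 3x3 convolutions; a
  final sigmoid yields a per-pixel vessel probability.

Everything runs on the NumPy autodiff core in :mod:`vesselseg.nn`; feature
maps at the public API are (H, W, C) arrays, NCHW internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import InvalidConfigError, InvalidInputError, InvalidShapeError

__all__ = [
    "ModelConfig",
    "BFCN",
    "effective_kernel_size",
    "receptive_field_support",
    "global_average_pool",
    "feature_reweight",
    "msie_block",
    "transfer_layer",
    "decoder_step",
    "bfcn_forward",
    "save_checkpoint",
    "load_checkpoint",
]


def effective_kernel_size(k: int, r: int) -> int:
    """Effective side length of a dilated convolution kernel.

    A k x k kernel with expansion rate r covers K = k + (k-1)(r-1) input
    pixels per side; r = 1 recovers the standard convolution.
    """
    k, r = int(k), int(r)
    if k < 1 or r < 1:
        raise InvalidConfigError(f"k and r must be >= 1, got k={k}, r={r}")
    return k + (k - 1) * (r - 1)


def receptive_field_support(k: int = 3, dilation: int = 2) -> int:
    """Measure the receptive field of one dilated conv layer empirically.

    Builds a single k x k convolution with the given dilation on a
    sufficiently large input, backpropagates from one central output pixel,
    and returns the side length of the bounding box of input pixels with
    nonzero gradient.  Equals ``effective_kernel_size(k, dilation)``.
    """
    K = effective_kernel_size(k, dilation)
    size = 4 * K + 1
    x = nn.parameter(np.zeros((1, 1, size, size)))
    w = nn.Tensor(np.ones((1, 1, k, k)))
    y = nn.conv2d(x, w, dilation=dilation)
    g = np.zeros_like(y.data)
    g[0, 0, size // 2, size // 2] = 1.0
    y.backward(g)
    rows = np.nonzero(np.abs(x.grad[0, 0]).sum(axis=1))[0]
    cols = np.nonzero(np.abs(x.grad[0, 0]).sum(axis=0))[0]
    side_r = rows.max() - rows.min() + 1
    side_c = cols.max() - cols.min() + 1
    if side_r != side_c:
        raise RuntimeError("anisotropic support; convolution is broken")
    return int(side_r)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth:          number of encoder levels (resolution halves per level).
    base_channels:  feature channels at the top level; doubles per level.
    dilation_rates: the 4 expansion rates of the MSIE branches (distinct).
    se_reduction:   bottleneck ratio of the channel-recalibration layer.
    side_input:     feed a downscaled input image into each encoder level.
    gate_mode:      'combined' multiplies both gates into the skip
                    (Y = beta * (alpha * X)); 'literal' applies only the
                    spatial gate to the raw features (Y = beta * X).
    seed:           weight-initialization seed (He fan-in scaling).
    """

    depth: int = 4
    base_channels: int = 32
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    se_reduction: int = 4
    side_input: bool = True
    gate_mode: str = "combined"
    seed: int = 0

    def __post_init__(self):
        if len(self.dilation_rates) != 4 or len(set(self.dilation_rates)) != 4:
            raise InvalidConfigError(
                f"dilation_rates must be 4 pairwise-distinct rates, "
                f"got {self.dilation_rates}")
        if any(r < 1 for r in self.dilation_rates):
            raise InvalidConfigError("dilation rates must be >= 1")
        if self.depth < 2:
            raise InvalidConfigError("depth must be >= 2")
        if self.gate_mode not in ("combined", "literal"):
            raise InvalidConfigError(f"unknown gate_mode {self.gate_mode!r}")

    @property
    def level_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _he_conv(rng, out_ch, in_ch, k, name, params, gain=2.0):
    fan_in = in_ch * k * k
    w = nn.parameter(rng.normal(0.0, np.sqrt(gain / fan_in), (out_ch, in_ch, k, k)),
                     name=f"{name}.w")
    b = nn.parameter(np.zeros(out_ch), name=f"{name}.b")
    params[f"{name}.w"] = w
    params[f"{name}.b"] = b
    return w, b


class SEBlock:
    """Channel recalibration: gate = sigmoid(F(global-avg-pool(X))); U = gate * X.

    F is a two-layer 1x1 bottleneck (reduction ratio ``reduction``) with an
    intermediate ReLU.  Since the gate lies in (0,1), recalibration never
    increases any channel's magnitude.
    """

    def __init__(self, rng, channels, reduction, name, params):
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.w1, self.b1 = _he_conv(rng, hidden, channels, 1, f"{name}.fc1", params)
        self.w2, self.b2 = _he_conv(rng, channels, hidden, 1, f"{name}.fc2", params)

    def gate(self, x: nn.Tensor) -> nn.Tensor:
        r = nn.global_avg_pool(x)
        r = nn.relu(nn.conv2d(r, self.w1, self.b1))
        return nn.sigmoid(nn.conv2d(r, self.w2, self.b2))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.shape[1] != self.channels:
            raise InvalidConfigError(
                f"SEBlock built for {self.channels} channels, got {x.data.shape[1]}")
        return nn.mul(x, self.gate(x))


class MSIEBlock:
    """Four parallel dilated 3x3 branches + a 1x1 branch, fused and recalibrated."""

    def __init__(self, rng, in_ch, out_ch, rates, reduction, name, params):
        self.rates = tuple(rates)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.branches = [
            _he_conv(rng, out_ch, in_ch, 3, f"{name}.dil{r}", params)
            for r in self.rates
        ]
        self.scale_w, self.scale_b = _he_conv(rng, out_ch, in_ch, 1,
                                              f"{name}.scale", params)
        self.proj_w, self.proj_b = _he_conv(rng, out_ch, 5 * out_ch, 1,
                                            f"{name}.proj", params)
        self.se = SEBlock(rng, out_ch, reduction, f"{name}.se", params)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        outs = [nn.relu(nn.conv2d(x, w, b, dilation=r))
                for (w, b), r in zip(self.branches, self.rates)]
        outs.append(nn.relu(nn.conv2d(x, self.scale_w, self.scale_b)))
        fused = nn.relu(nn.conv2d(nn.concat(outs, axis=1), self.proj_w, self.proj_b))
        return self.se(fused)


class TransferLayer:
    """Gated skip connection.

    Stage 1 pools the feature map spatially (max and mean) to two 1x1xC
    descriptors, passes each through a 1x1 convolution and their sum through
    a sigmoid, giving the channel gate alpha.  Stage 2 takes per-pixel
    channel max and mean of alpha*X, passes each through a 1x1 convolution
    and their sum through a sigmoid, giving the spatial gate beta.  A fifth
    1x1 convolution projects the gated map to the skip width.
    """

    def __init__(self, rng, channels, out_ch, name, params):
        self.channels = channels
        self.cmax_w, self.cmax_b = _he_conv(rng, channels, channels, 1,
                                            f"{name}.cmax", params)
        self.cmean_w, self.cmean_b = _he_conv(rng, channels, channels, 1,
                                              f"{name}.cmean", params)
        self.smax_w, self.smax_b = _he_conv(rng, 1, 1, 1, f"{name}.smax", params)
        self.smean_w, self.smean_b = _he_conv(rng, 1, 1, 1, f"{name}.smean", params)
        self.out_w, self.out_b = _he_conv(rng, out_ch, channels, 1,
                                          f"{name}.out", params)

    def gates(self, x: nn.Tensor, gate_mode: str = "combined"):
        """Return (alpha, beta, Y) with Y the gated map before the final 1x1."""
        xmax = nn.conv2d(nn.global_max_pool(x), self.cmax_w, self.cmax_b)
        xmean = nn.conv2d(nn.global_avg_pool(x), self.cmean_w, self.cmean_b)
        alpha = nn.sigmoid(nn.add(xmax, xmean))          # (N,C,1,1)
        ax = nn.mul(alpha, x)
        smax = nn.conv2d(nn.channel_max(ax), self.smax_w, self.smax_b)
        smean = nn.conv2d(nn.channel_mean(ax), self.smean_w, self.smean_b)
        beta = nn.sigmoid(nn.add(smax, smean))           # (N,1,H,W)
        if gate_mode == "combined":
            y = nn.mul(ax, beta)
        elif gate_mode == "literal":
            y = nn.mul(x, beta)
        else:
            raise InvalidConfigError(f"unknown gate_mode {gate_mode!r}")
        return alpha, beta, y

    def __call__(self, x: nn.Tensor, gate_mode: str = "combined") -> nn.Tensor:
        _, _, y = self.gates(x, gate_mode)
        return nn.conv2d(y, self.out_w, self.out_b)


class DecoderStep:
    """Deconv x2 upsampling, concat with the gated skip, two 3x3 convolutions."""

    def __init__(self, rng, deep_ch, skip_ch, out_ch, name, params):
        fan_in = deep_ch * 4
        self.up_w = nn.parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (deep_ch, out_ch, 2, 2)),
            name=f"{name}.up.w")
        self.up_b = nn.parameter(np.zeros(out_ch), name=f"{name}.up.b")
        params[f"{name}.up.w"] = self.up_w
        params[f"{name}.up.b"] = self.up_b
        self.c1_w, self.c1_b = _he_conv(rng, out_ch, out_ch + skip_ch, 3,
                                        f"{name}.c1", params)
        self.c2_w, self.c2_b = _he_conv(rng, out_ch, out_ch, 3, f"{name}.c2", params)

    def __call__(self, deep: nn.Tensor, skip: nn.Tensor) -> nn.Tensor:
        up = nn.relu(nn.conv_transpose2d(deep, self.up_w, self.up_b))
        if up.data.shape[2:] != skip.data.shape[2:]:
            raise InvalidShapeError(
                f"upsampled map {up.data.shape[2:]} does not match skip "
                f"{skip.data.shape[2:]}")
        x = nn.concat([up, skip], axis=1)
        x = nn.relu(nn.conv2d(x, self.c1_w, self.c1_b))
        return nn.relu(nn.conv2d(x, self.c2_w, self.c2_b))


class BFCN:
    """The full butterfly network.  Input (N,1,H,W) in [0,1] -> (N,1,H,W) probs."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: dict[str, nn.Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.level_channels
        side_ch = max(2, cfg.base_channels // 2) if cfg.side_input else 0

        self.encoders: list[MSIEBlock] = []
        self.side_lifts: list[tuple] = []
        in_ch = 1
        for lvl, out_ch in enumerate(chans):
            if cfg.side_input and lvl > 0:
                self.side_lifts.append(
                    _he_conv(rng, side_ch, 1, 3, f"side{lvl}", self.params))
                in_ch += side_ch
            self.encoders.append(
                MSIEBlock(rng, in_ch, out_ch, cfg.dilation_rates,
                          cfg.se_reduction, f"enc{lvl}", self.params))
            in_ch = out_ch

        self.transfers = [
            TransferLayer(rng, chans[lvl], chans[lvl], f"tl{lvl}", self.params)
            for lvl in range(cfg.depth - 1)
        ]
        self.decoders = [
            DecoderStep(rng, chans[lvl + 1], chans[lvl], chans[lvl],
                        f"dec{lvl}", self.params)
            for lvl in range(cfg.depth - 1)
        ]
        self.head_w, self.head_b = _he_conv(rng, 1, chans[0], 1, "head", self.params)

    # -- forward ---------------------------------------------------------
    def forward(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.cfg
        n, c, h, w = x.data.shape
        div = 2 ** (cfg.depth - 1)
        if c != 1:
            raise InvalidInputError(f"expected 1 input channel, got {c}")
        if h % div or w % div:
            raise InvalidShapeError(
                f"spatial dims ({h}, {w}) must be divisible by {div}; "
                f"pad to ({-(-h // div) * div}, {-(-w // div) * div})")
        skips = []
        feat = x
        for lvl, enc in enumerate(self.encoders):
            if lvl > 0:
                feat = nn.max_pool2d(feat)
                if cfg.side_input:
                    side = nn.avg_pool2d(x, 2 ** lvl)
                    sw, sb = self.side_lifts[lvl - 1]
                    side = nn.relu(nn.conv2d(side, sw, sb))
                    feat = nn.concat([feat, side], axis=1)
            feat = enc(feat)
            if lvl < cfg.depth - 1:
                skips.append(feat)
        for lvl in range(cfg.depth - 2, -1, -1):
            gated = self.transfers[lvl](skips[lvl], cfg.gate_mode)
            feat = self.decoders[lvl](feat, gated)
        logits = nn.conv2d(feat, self.head_w, self.head_b)
        return nn.sigmoid(logits)

    def predict(self, img: np.ndarray) -> np.ndarray:
        """Probability map for one (H, W) image or a (N, H, W) batch."""
        img = np.asarray(img, dtype=np.float64)
        single = img.ndim == 2
        if single:
            img = img[None]
        x = nn.Tensor(img[:, None, :, :])
        p = self.forward(x).data[:, 0]
        return p[0] if single else p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())


# ---------------------------------------------------------------------------
# functional wrappers over (H, W, C) feature maps — thin, test-facing
# ---------------------------------------------------------------------------

def _to_nchw(X: np.ndarray) -> nn.Tensor:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise InvalidInputError(f"FeatureMap must be (H, W, C), got {X.shape}")
    if X.size == 0:
        raise InvalidInputError("empty feature map")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("feature map contains non-finite values")
    return nn.Tensor(X.transpose(2, 0, 1)[None])


def _to_hwc(t: nn.Tensor) -> np.ndarray:
    return t.data[0].transpose(1, 2, 0)


def global_average_pool(X: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of an (H, W, C) map, returned as (1, 1, C)."""
    return _to_hwc(nn.global_avg_pool(_to_nchw(X)))


def feature_reweight(X: np.ndarray, se: SEBlock) -> np.ndarray:
    """Apply channel recalibration to an (H, W, C) map."""
    t = _to_nchw(X)
    if t.data.shape[1] != se.channels:
        raise InvalidConfigError(
            f"recalibration built for {se.channels} channels, "
            f"got {t.data.shape[1]}")
    return _to_hwc(se(t))


def msie_block(X: np.ndarray, block: MSIEBlock) -> np.ndarray:
    """Apply a multiscale extraction block to an (H, W, C) map."""
    return _to_hwc(block(_to_nchw(X)))


def transfer_layer(X: np.ndarray, layer: TransferLayer,
                   gate_mode: str = "combined") -> np.ndarray:
    """Apply a gated skip connection to an (H, W, C) map."""
    return _to_hwc(layer(_to_nchw(X), gate_mode))


def decoder_step(deep: np.ndarray, skip: np.ndarray, step: DecoderStep) -> np.ndarray:
    """One upsample-concat-refine decoder stage on (H, W, C) maps."""
    d, s = _to_nchw(deep), _to_nchw(skip)
    if (d.data.shape[2] * 2, d.data.shape[3] * 2) != s.data.shape[2:]:
        raise InvalidShapeError(
            f"deep spatial dims {d.data.shape[2:]} must be half of skip "
            f"{s.data.shape[2:]}")
    return _to_hwc(step(d, s))


def bfcn_forward(img: np.ndarray, model: BFCN) -> np.ndarray:
    """Probability map for an (H, W) enhanced image or patch."""
    return model.predict(img)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _ckpt_paths(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    return path, Path(str(path) + ".json")


def save_checkpoint(model: BFCN, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON sidecar with the ModelConfig."""
    path, sidecar = _ckpt_paths(path)
    np.savez(path, **{k: p.data for k, p in model.params.items()})
    cfg = asdict(model.cfg)
    cfg["dilation_rates"] = list(cfg["dilation_rates"])
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> BFCN:
    path, sidecar = _ckpt_paths(path)
    cfg_d = json.loads(sidecar.read_text())
    cfg_d["dilation_rates"] = tuple(cfg_d["dilation_rates"])
    model = BFCN(ModelConfig(**cfg_d))
    with np.load(path) as data:
        for k, p in model.params.items():
            p.data = data[k].astype(np.float64)
    return model
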