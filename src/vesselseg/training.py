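"""Patch-based training: cross-entropy loss, Adam, plateau LR decay.

The reference recipe trains on randomly extracted patches (batch 16) with
Adam (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8) and decays the learning
rate by a plateau rule when the monitored loss stops improving.  The loss
is pixelwise binary cross-entropy, summed over pixels and averaged over
the batch; predictions are clipped away from {0, 1} before the logarithm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import DivergenceError, InvalidInputError
from .model import BFCN, ModelConfig

__all__ = [
    "TrainConfig",
    "TrainResult",
    "PlateauScheduler",
    "cross_entropy_loss",
    "sample_patches_from_triples",
    "train",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 200
    batch: int = 16
    patches_per_set: int = 10480
    patch_size: int = 128
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    val_fraction: float = 0.0
    seed: int = 0
    clip: float = 1e-7


@dataclass
class TrainResult:
    model: BFCN
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss", "lr"])
            for i, (l, r) in enumerate(zip(self.loss_history, self.lr_history)):
                w.writerow([i, l, r])


def cross_entropy_loss(y: np.ndarray, yhat: np.ndarray,
                       clip: float = 1e-7) -> float:
    """Binary cross-entropy: sum over pixels, mean over batch elements.

    ``y`` holds {0,1} labels; ``yhat`` probabilities, clipped to
    [clip, 1-clip].  Arrays of equal shape; the leading axis (if ndim > 2)
    is the batch.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise InvalidInputError(
            f"label shape {y.shape} != prediction shape {yhat.shape}")
    batch = y.shape[0] if y.ndim > 2 else 1
    p = np.clip(yhat, clip, 1.0 - clip)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum() / batch)


class PlateauScheduler:
    """Multiply the optimizer lr by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss (relative threshold 1e-4)."""

    def __init__(self, optimizer: nn.Adam, factor: float = 0.1,
                 patience: int = 10, threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = float(factor)
        self.patience = int(patience)
        self.threshold = float(threshold)
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> float:
        """Report an epoch loss; returns the (possibly decayed) lr."""
        if loss < self.best * (1.0 - self.threshold):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0
        return self.opt.lr


def sample_patches_from_triples(triples, cfg: TrainConfig):
    """Enhance each (FundusImage, truth, fov) triple and sample patches.

    Distributes ``cfg.patches_per_set`` patch pairs evenly over the images,
    FOV-constrained; used by the CLI train command.
    """
    from .patching import sample_training_patches
    from .preprocessing import preprocess

    if not triples:
        raise InvalidInputError("empty dataset")
    per_img = max(1, cfg.patches_per_set // len(triples))
    pairs = []
    for i, (img, truth, fov) in enumerate(triples):
        enhanced = preprocess(img)
        pairs.extend(sample_training_patches(
            enhanced.pixels, truth, per_img, size=cfg.patch_size,
            seed=cfg.seed + i, fov=fov))
    return pairs


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          dataset, progress=None) -> TrainResult:
    """Train a BFCN on (patch, label) pairs.

    ``dataset`` is a sequence of (image_patch, label_patch) 2-D arrays of
    identical shapes.  Patches are shuffled each epoch with the config
    seed; the per-epoch mean loss and the learning-rate trace are
    recorded.  Raises :class:`DivergenceError` on a non-finite loss.
    """
    pairs = list(dataset)
    if not pairs:
        raise InvalidInputError("empty training dataset")
    model = BFCN(model_cfg)
    opt = nn.Adam(model.params, lr=train_cfg.lr, beta1=train_cfg.beta1,
                  beta2=train_cfg.beta2, eps=train_cfg.eps)
    sched = PlateauScheduler(opt, factor=train_cfg.plateau_factor,
                             patience=train_cfg.plateau_patience)
    rng = np.random.default_rng(train_cfg.seed)

    n_val = int(round(train_cfg.val_fraction * len(pairs)))
    val_pairs = pairs[:n_val]
    fit_pairs = pairs[n_val:]
    result = TrainResult(model=model)

    imgs = np.stack([p[0] for p in fit_pairs])[:, None]   # (N,1,H,W)
    labs = np.stack([np.asarray(p[1], dtype=np.float64) for p in fit_pairs])[:, None]

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(fit_pairs))
        losses = []
        for start in range(0, len(order), train_cfg.batch):
            idx = order[start:start + train_cfg.batch]
            x = nn.Tensor(imgs[idx])
            prob = model.forward(x)
            loss = nn.bce_loss(prob, labs[idx], clip=train_cfg.clip)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {start}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        result.loss_history.append(mean_loss)
        result.lr_history.append(sched.step(mean_loss))
        if val_pairs:
            vprob = model.predict(np.stack([p[0] for p in val_pairs]))
            vlab = np.stack([np.asarray(p[1], dtype=np.float64)
                             for p in val_pairs])
            result.val_history.append(cross_entropy_loss(vlab, vprob))
        if progress is not None:
            progress(epoch, mean_loss, opt.lr)
    return result
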