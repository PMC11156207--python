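"""Training loop, AdamW optimizer and inference wrapper for the U-Net.

The recipe: per-pixel binary cross-entropy averaged over the three output
channels, AdamW (lr 5e-4, weight decay 1e-8), and the global gradient
norm clamped to 3 before every step. The default schedule is 40 epochs;
scaled-down experiments on synthetic data use more epochs at smaller
image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..core import BScan, SegmentationOutput
from ..fovea import FoveaTargetConfig, build_fovea_target
from .augment import AugmentationConfig, augment_sample
from .unet import UNet, UNetConfig

__all__ = ["TrainConfig", "AdamW", "bce_with_logits", "train_model", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    lr: float = 5e-4
    weight_decay: float = 1e-8
    grad_norm_clip: float = 3.0
    batch_size: int = 8
    seed: int = 0
    mixed_precision: bool = False  # reserved; computation runs in float32

    def __post_init__(self) -> None:
        if self.lr < 0 or self.weight_decay < 0:
            raise ValueError("lr and weight_decay must be >= 0")
        if self.grad_norm_clip <= 0:
            raise ValueError("grad_norm_clip must be positive")


class AdamW:
    """Decoupled-weight-decay Adam over a U-Net's parameter list."""

    def __init__(self, model: UNet, lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in model.parameters()]
        self.v = [np.zeros_like(l.params[n]) for l, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            p = layer.params[name]
            p -= (self.lr * (update + self.wd * p)).astype(p.dtype)


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all pixels and channels.

    Returns the loss and its gradient w.r.t. the logits. Uses the
    log-sum-exp form for numerical stability.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - t * z))
    dz = (1.0 / (1.0 + np.exp(-z)) - t) / z.size
    return loss, dz


def build_targets(
    samples, fovea_config: FoveaTargetConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack images and (region, vessel, fovea-target) channels for training."""
    images = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    targets = np.stack(
        [
            np.stack(
                [
                    s.region_mask.astype(np.float32),
                    s.vessel_mask.astype(np.float32),
                    build_fovea_target(
                        s.image.shape, s.fovea_col, s.fovea_row, fovea_config
                    ).astype(np.float32),
                ]
            )
            for s in samples
        ]
    )
    return images, targets


def train_model(
    model: UNet,
    dataset,
    tcfg: TrainConfig | None = None,
    acfg: AugmentationConfig | None = None,
    fovea_config: FoveaTargetConfig | None = None,
) -> tuple[UNet, dict]:
    """Train ``model`` on a list of synthetic samples.

    Each step: (augment ->) forward -> mean BCE over the three channels ->
    clip the global gradient norm at ``grad_norm_clip`` -> AdamW update.
    Returns the model and a history dict with per-epoch mean loss and the
    per-step gradient norms before and after clipping. Aborts with
    diagnostics if the loss turns non-finite.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    tcfg = tcfg or TrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    images, targets = build_targets(dataset, fovea_config)
    fovea_cols = np.array([s.fovea_col for s in dataset])

    opt = AdamW(model, tcfg.lr, tcfg.weight_decay)
    history: dict = {"loss": [], "grad_norm": [], "grad_norm_preclip": []}
    n = images.shape[0]
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, tb = images[idx], targets[idx]
            if acfg is not None:
                xs, ts = [], []
                for i in range(len(idx)):
                    aug_seed = int(rng.integers(0, 2**31 - 1))
                    xi, ti, _ = augment_sample(
                        xb[i, 0], tb[i], int(fovea_cols[idx[i]]), acfg, aug_seed
                    )
                    xs.append(xi.astype(np.float32))
                    ts.append(ti.astype(np.float32))
                xb = np.stack(xs)[:, None]
                tb = np.stack(ts)
            logits = model.forward(xb, training=True)
            loss, dz = bce_with_logits(logits, tb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]"
                )
            model.zero_grad()
            model.backward(dz)
            norm = model.grad_norm()
            history["grad_norm_preclip"].append(norm)
            clip = tcfg.grad_norm_clip
            if norm > clip:
                scale = clip / norm
                for layer, name in model.parameters():
                    layer.grads[name] *= scale
                norm = model.grad_norm()
            history["grad_norm"].append(norm)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
    return model, history


def predict(model: UNet, bscan: BScan | np.ndarray) -> SegmentationOutput:
    """Sigmoid probability maps for one scan, padding to a multiple of 64.

    Inputs whose sides are not divisible by the network stride are
    reflect-padded for the forward pass and the output is cropped back.
    """
    img = bscan.image if isinstance(bscan, BScan) else np.asarray(bscan, float)
    h, w = img.shape
    div = model.config.divisor
    ph = (-h) % div
    pw = (-w) % div
    padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
    probs = model.predict_proba(padded[None, None].astype(np.float32))[0]
    probs = probs[:, :h, :w]
    return SegmentationOutput(
        region_prob=probs[0], vessel_prob=probs[1], fovea_prob=probs[2]
    )


def save_checkpoint(model: UNet, path: str | Path) -> None:
    cfg = model.config
    np.savez_compressed(
        Path(path),
        __depth=cfg.depth,
        __encoder_channels=np.array(cfg.encoder_channels),
        __out_channels=cfg.out_channels,
        __in_channels=cfg.in_channels,
        **model.state_dict(),
    )


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        cfg = UNetConfig(
            depth=int(data["__depth"]),
            encoder_channels=tuple(int(c) for c in data["__encoder_channels"]),
            out_channels=int(data["__out_channels"]),
            in_channels=int(data["__in_channels"]),
        )
        model = UNet(cfg, seed=0)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        model.load_state_dict(state)
    return model
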