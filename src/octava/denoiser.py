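"""Learned single-shot denoiser trained against averaged-frame teachers.

The central idea: a multi-frame averaged angiogram is a low-noise version
of the same field a single shot sees, so pairs (single shot, registered
average) of the *same eye* form a supervised training set without any
manually cleaned ground truth.  A small U-Net is trained on aligned image
patches to regress the teacher intensities, and is then applied to a full
single-shot image by overlapping tiled inference.

All randomness (weight init, batch sampling) flows from the config seed,
so training and inference are exactly reproducible run-to-run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._unet import UNet
from .core_io import EnFaceImage

__all__ = [
    "DenoiserConfig",
    "TrainingPairSet",
    "TrainedDenoiser",
    "extract_patches",
    "concat_pair_sets",
    "train_denoiser",
    "denoise_image",
    "save_denoiser",
    "load_denoiser",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class DenoiserConfig:
    """Hyperparameters of the denoising network and its training run.

    depth:
        Down/up-sampling scales of the U-Net (patch_px must be divisible
        by ``2**depth``).
    base_channels:
        Feature channels at the finest scale.
    patch_px / stride_px:
        Training patch size and extraction stride in pixels.
    loss:
        ``"l1"`` (robust to speckle outliers, default) or ``"l2"``.
    """

    depth: int = 3
    base_channels: int = 16
    patch_px: int = 64
    stride_px: int = 32
    loss: str = "l1"
    learning_rate: float = 2e-3
    batch_size: int = 16
    n_steps: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_px % (2**self.depth) != 0:
            raise ValueError("patch_px must be divisible by 2**depth")
        if self.stride_px > self.patch_px or self.stride_px < 1:
            raise ValueError("stride_px must lie in [1, patch_px]")
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")


@dataclass
class TrainingPairSet:
    """Aligned (noisy, teacher) patch pairs normalized to [0, 1].

    ``noisy`` and ``teacher`` are (N, patch, patch) float32 arrays cut at
    identical origins of the same eye; ``provenance`` records
    (eye id, row origin, col origin) per pair.
    """

    noisy: np.ndarray
    teacher: np.ndarray
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noisy.shape != self.teacher.shape:
            raise ValueError("noisy and teacher arrays must have equal shape")

    def __len__(self) -> int:
        return int(self.noisy.shape[0])


@dataclass
class TrainedDenoiser:
    """A trained network plus its config and loss history."""

    net: UNet
    config: DenoiserConfig
    loss_history: list[float]

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


def _grid_origins(extent: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, extent - patch + 1, stride))
    if origins[-1] != extent - patch:
        origins.append(extent - patch)  # last tile shifted inward to fit
    return origins


def extract_patches(
    original: EnFaceImage,
    averaged: EnFaceImage,
    config: DenoiserConfig,
    eye_id: str = "",
) -> TrainingPairSet:
    """Cut a regular grid of aligned patch pairs from one eye's images."""
    if original.pixels.shape != averaged.pixels.shape:
        raise ValueError("original and averaged images must share dimensions")
    h, w = original.pixels.shape
    p = config.patch_px
    if h < p or w < p:
        raise ValueError(f"image ({h}x{w}) smaller than patch size {p}")
    rows = _grid_origins(h, p, config.stride_px)
    cols = _grid_origins(w, p, config.stride_px)
    noisy = original.astype_float() / 255.0
    teach = averaged.astype_float() / 255.0
    xs, ts, prov = [], [], []
    for r in rows:
        for c in cols:
            xs.append(noisy[r : r + p, c : c + p])
            ts.append(teach[r : r + p, c : c + p])
            prov.append((eye_id, r, c))
    return TrainingPairSet(
        noisy=np.stack(xs).astype(np.float32),
        teacher=np.stack(ts).astype(np.float32),
        provenance=prov,
    )


def concat_pair_sets(sets: list[TrainingPairSet]) -> TrainingPairSet:
    """Pool patch pairs from several eyes into one training set."""
    if not sets:
        raise ValueError("no pair sets to concatenate")
    return TrainingPairSet(
        noisy=np.concatenate([s.noisy for s in sets]),
        teacher=np.concatenate([s.teacher for s in sets]),
        provenance=[p for s in sets for p in s.provenance],
    )


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    diff = pred - target
    n = diff.size
    if kind == "l1":
        return float(np.abs(diff).mean()), np.sign(diff) / n
    return float((diff**2).mean()), 2.0 * diff / n


def train_denoiser(pairs: TrainingPairSet, config: DenoiserConfig) -> TrainedDenoiser:
    """Train the U-Net by Adam on minibatches of patch pairs.

    Minimizes the configured pixelwise loss between ``net(noisy)`` and the
    teacher patch.  Returns the network with its per-step loss history.

    Raises
    ------
    ValueError
        If there are no pairs or ``n_steps`` is 0.
    RuntimeError
        If the loss becomes non-finite (reported with its step index).
    """
    if len(pairs) < 1:
        raise ValueError("training requires at least one pair")
    if config.n_steps < 1:
        raise ValueError("no training performed: n_steps must be >= 1")

    ss = np.random.SeedSequence(config.seed)
    init_rng, batch_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    net = UNet(config.depth, config.base_channels, init_rng)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    # float32 end to end: halves memory traffic, ample precision for image loss
    for k in net.params:
        net.params[k] = net.params[k].astype(np.float32)
        m[k] = m[k].astype(np.float32)
        v[k] = v[k].astype(np.float32)
    x_all = pairs.noisy.astype(np.float32)[:, None]  # (N, 1, p, p)
    t_all = pairs.teacher.astype(np.float32)[:, None]
    n = len(pairs)
    history: list[float] = []
    for step in range(1, config.n_steps + 1):
        idx = batch_rng.integers(0, n, size=min(config.batch_size, n))
        pred = net.forward(x_all[idx])
        loss, dpred = _loss_and_grad(pred, t_all[idx], config.loss)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at step {step}")
        history.append(loss)
        grads = net.backward(dpred)
        for k in net.params:
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1**step)
            vhat = v[k] / (1 - b2**step)
            net.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    net._cache.clear()
    return TrainedDenoiser(net=net, config=config, loss_history=history)


def denoise_image(model: TrainedDenoiser, image: EnFaceImage) -> EnFaceImage:
    """Denoise a full image by overlap-averaged tiled inference.

    Tiles of ``patch_px`` at stride ``patch_px // 2`` cover the image (the
    last row/column of tiles shifted inward); overlapping predictions are
    blended with uniform weights, then clipped and quantized to 8 bits.
    """
    h, w = image.pixels.shape
    p = model.config.patch_px
    if h < p or w < p:
        raise ValueError(f"image ({h}x{w}) smaller than patch size {p}")
    stride = max(p // 2, 1)
    rows = _grid_origins(h, p, stride)
    cols = _grid_origins(w, p, stride)
    x = image.astype_float() / 255.0
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    tiles = [(r, c) for r in rows for c in cols]
    batch = 16
    dtype = next(iter(model.net.params.values())).dtype
    for i in range(0, len(tiles), batch):
        chunk = tiles[i : i + batch]
        xb = np.stack([x[r : r + p, c : c + p] for r, c in chunk])[:, None].astype(dtype)
        yb = model.net.predict(xb)[:, 0]
        for (r, c), y in zip(chunk, yb):
            acc[r : r + p, c : c + p] += y
            cnt[r : r + p, c : c + p] += 1.0
    out = acc / cnt
    px = np.rint(np.clip(out, 0.0, 1.0) * 255.0).astype(np.uint8)
    return EnFaceImage(
        pixels=px,
        mm_per_pixel=image.mm_per_pixel,
        label="denoised",
        seed=image.seed,
        provenance="denoise_image",
    )


def save_denoiser(model: TrainedDenoiser, path: str | Path) -> None:
    """Write a single-file checkpoint: weights + config JSON + format version."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "loss_history": model.loss_history,
    }
    arrays = {f"param.{k}": val for k, val in model.net.params.items()}
    with open(path, "wb") as f:
        np.savez(f, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_denoiser(path: str | Path) -> TrainedDenoiser:
    """Reload a checkpoint bit-compatibly with the in-memory model."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = DenoiserConfig(**meta["config"])
        net = UNet(config.depth, config.base_channels, np.random.default_rng(0))
        for k in list(net.params):
            net.params[k] = z[f"param.{k}"].copy()
    return TrainedDenoiser(net=net, config=config, loss_history=list(meta["loss_history"]))
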