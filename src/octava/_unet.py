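"""A small U-Net implemented directly on numpy arrays.

Encoder–decoder with skip connections by concatenation: each scale applies
two 3x3 same-padding convolutions with ReLU, 2x2 average pooling going
down and nearest-neighbor upsampling coming up, and a final linear 1x1
convolution producing one output channel.  Forward and backward passes are
hand-written (im2col + BLAS matmul), which keeps the network fully
deterministic for a fixed seed and dependency-free beyond numpy.

Tensors are (N, C, H, W) float64 throughout; parameters live in a flat
``{name: array}`` dict so optimizers and checkpoints stay trivial.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*9) patches of the 1-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9))


def _col2im(dcols: np.ndarray, xshape: tuple[int, int, int, int]) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, 3, 3)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1 : h + 1, 1 : w + 1]


def _conv3_forward(x, W, b):
    n, c, h, w = x.shape
    cols = _im2col(x)  # (N, H*W, C*9)
    y = (cols.reshape(n * h * w, -1) @ W.T + b).reshape(n, h * w, W.shape[0])
    y = y.transpose(0, 2, 1).reshape(n, W.shape[0], h, w)
    return y, (cols, x.shape)


def _conv3_backward(dy, W, cache):
    cols, xshape = cache
    n, f, h, w = dy.shape
    dyf = np.ascontiguousarray(dy.reshape(n, f, h * w).transpose(0, 2, 1)).reshape(n * h * w, f)
    cols2d = cols.reshape(n * h * w, -1)
    dW = dyf.T @ cols2d
    db = dyf.sum(axis=0)
    dcols = (dyf @ W).reshape(n, h * w, -1)
    dx = _col2im(dcols, xshape)
    return dx, dW, db


def _pool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_backward(dy):
    return dy.repeat(2, axis=2).repeat(2, axis=3) / 4.0


def _up2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """U-Net regression network: one input channel, one linear output channel.

    Parameters
    ----------
    depth:
        Number of down/up-sampling scales; inputs must be divisible by
        ``2**depth`` in each dimension.
    base_channels:
        Channels at the finest scale; doubled at each deeper scale.
    rng:
        Generator used for He-normal weight initialization.
    """

    def __init__(self, depth: int, base_channels: int, rng: np.random.Generator):
        self.depth = depth
        self.base_channels = base_channels
        self.params: dict[str, np.ndarray] = {}
        self._cache: dict[str, object] = {}

        def add_conv(name: str, cin: int, cout: int, k: int = 3):
            fan_in = cin * k * k
            self.params[f"{name}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
            self.params[f"{name}_b"] = np.zeros(cout)

        ch = lambda i: base_channels * (2**i)
        for i in range(depth):
            add_conv(f"enc{i}_c1", 1 if i == 0 else ch(i - 1), ch(i))
            add_conv(f"enc{i}_c2", ch(i), ch(i))
        add_conv("bott_c1", ch(depth - 1), ch(depth))
        add_conv("bott_c2", ch(depth), ch(depth))
        for i in range(depth):
            add_conv(f"dec{i}_c1", ch(i + 1) + ch(i), ch(i))
            add_conv(f"dec{i}_c2", ch(i), ch(i))
        add_conv("head", ch(0), 1, k=1)

    # -- blocks ------------------------------------------------------------

    def _block(self, name: str, x: np.ndarray) -> np.ndarray:
        p = self.params
        y1, c1 = _conv3_forward(x, p[f"{name}_c1_W"], p[f"{name}_c1_b"])
        a1 = np.maximum(y1, 0.0)
        y2, c2 = _conv3_forward(a1, p[f"{name}_c2_W"], p[f"{name}_c2_b"])
        a2 = np.maximum(y2, 0.0)
        self._cache[name] = (c1, a1, c2, a2)
        return a2

    def _block_backward(self, name: str, da2: np.ndarray, grads: dict) -> np.ndarray:
        p = self.params
        c1, a1, c2, a2 = self._cache[name]
        dy2 = da2 * (a2 > 0)
        da1, dW2, db2 = _conv3_backward(dy2, p[f"{name}_c2_W"], c2)
        dy1 = da1 * (a1 > 0)
        dx, dW1, db1 = _conv3_backward(dy1, p[f"{name}_c1_W"], c1)
        grads[f"{name}_c2_W"] = dW2
        grads[f"{name}_c2_b"] = db2
        grads[f"{name}_c1_W"] = dW1
        grads[f"{name}_c1_b"] = db1
        return dx

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) in [0, 1]; returns (N, 1, H, W) linear output."""
        n, _, h, w = x.shape
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(f"input dims must be divisible by {2**self.depth}")
        skips = []
        hcur = x
        for i in range(self.depth):
            hcur = self._block(f"enc{i}", hcur)
            skips.append(hcur)
            hcur = _pool2(hcur)
        hcur = self._block("bott", hcur)
        for i in reversed(range(self.depth)):
            up = _up2(hcur)
            hcur = np.concatenate([up, skips[i]], axis=1)
            self._cache[f"dec{i}_split"] = up.shape[1]
            hcur = self._block(f"dec{i}", hcur)
        # linear 1x1 head
        p = self.params
        nh, ch_, hh, wh = hcur.shape
        flat = hcur.transpose(0, 2, 3, 1).reshape(-1, ch_)
        out = flat @ p["head_W"].T + p["head_b"]
        self._cache["head"] = (flat, hcur.shape)
        return out.reshape(nh, hh, wh, 1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/d(output); returns gradients per parameter."""
        grads: dict[str, np.ndarray] = {}
        p = self.params
        flat, hshape = self._cache["head"]
        n, _, hh, wh = dout.shape
        dflat_out = dout.transpose(0, 2, 3, 1).reshape(-1, 1)
        grads["head_W"] = dflat_out.T @ flat
        grads["head_b"] = dflat_out.sum(axis=0)
        dh = (dflat_out @ p["head_W"]).reshape(n, hh, wh, hshape[1]).transpose(0, 3, 1, 2)

        for i in range(self.depth):
            dh = self._block_backward(f"dec{i}", dh, grads)
            split = self._cache[f"dec{i}_split"]
            dup, dskip = dh[:, :split], dh[:, split:]
            dh = _up2_backward(dup)
            # stash skip gradient to merge on the way up the encoder
            self._cache[f"dskip{i}"] = dskip
        dh = self._block_backward("bott", dh, grads)
        for i in reversed(range(self.depth)):
            dh = _pool2_backward(dh)
            dh = dh + self._cache[f"dskip{i}"]
            dh = self._block_backward(f"enc{i}", dh, grads)
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without keeping caches alive longer than needed."""
        y = self.forward(x)
        self._cache.clear()
        return y
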