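"""Minimal convolutional classifiers for image crops.

Two tiny architectures are used on 39 x 69 crops of the straightened
epithelium: a one-stage network (conv 5x5 -> 60 maps, ReLU, fully
connected, softmax over 3 classes) that assigns OHC candidates to rows,
and a two-stage network (conv 60 -> conv 20 maps) that decides whether a
row gap contains an undetected cell.  Implemented directly on numpy
(im2col convolutions, softmax cross-entropy, SGD with momentum); the
training sets are small enough that this trains in seconds to minutes on
one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyConvNet"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, oh, ow, C, k, k)
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n, oh, ow, -1)


class _Conv:
    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * in_c))
        self.W = rng.normal(0.0, scale, (k * k * in_c, out_c)).astype(np.float32)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.k, self.in_c, self.out_c = k, in_c, out_c
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        z = self.cols @ self.W + self.b
        self.mask = z > 0
        return np.where(self.mask, z, 0.0)

    def backward(self, dout, need_dx: bool = True):
        dout = dout * self.mask
        n, oh, ow, _ = dout.shape
        cols2 = self.cols.reshape(-1, self.W.shape[0])
        d2 = dout.reshape(-1, self.out_c)
        self.dW = cols2.T @ d2 / n
        self.db = d2.mean(axis=0) * oh * ow
        if not need_dx:  # first layer: input gradient is never used
            return None
        dcols = (d2 @ self.W.T).reshape(n, oh, ow, self.k, self.k, self.in_c)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    def step(self, lr, mom):
        self.vW = mom * self.vW - lr * self.dW
        self.vb = mom * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class TinyConvNet:
    """Small conv net: N conv+ReLU stages, one dense layer, softmax.

    ``conv_channels=(60,)`` gives the 3-class row classifier,
    ``conv_channels=(60, 20)`` the binary gap classifier.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (69, 39),   # (H, W): r across rows, s along
        conv_channels: tuple[int, ...] = (60,),
        n_classes: int = 3,
        kernel: int = 5,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_shape = input_shape
        self.n_classes = n_classes
        self.convs = []
        h, w, c = input_shape[0], input_shape[1], 1
        for out_c in conv_channels:
            self.convs.append(_Conv(c, out_c, kernel, rng))
            h, w, c = h - kernel + 1, w - kernel + 1, out_c
        self.fc_W = rng.normal(0.0, np.sqrt(2.0 / (h * w * c)), (h * w * c, n_classes)).astype(
            np.float32
        )
        self.fc_b = np.zeros(n_classes, dtype=np.float32)
        self.v_fcW = np.zeros_like(self.fc_W)
        self.v_fcb = np.zeros_like(self.fc_b)

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32)
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True) + 1e-6
        return (x - mu) / sd

    def _forward(self, x):
        a = x[..., None]
        for conv in self.convs:
            a = conv.forward(a)
        self._flat_shape = a.shape
        flat = a.reshape(len(a), -1)
        self._flat = flat
        logits = flat @ self.fc_W + self.fc_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, crops: np.ndarray, batch: int = 32) -> np.ndarray:
        # batch stays small: the im2col patch tensor of the second conv
        # stage scales with batch * oh * ow * k^2 * channels
        """Class probabilities for (N, H, W) crops (standardized per crop)."""
        crops = self._standardize(np.atleast_3d(crops).reshape(-1, *self.input_shape))
        out = np.empty((len(crops), self.n_classes), dtype=np.float32)
        for i in range(0, len(crops), batch):
            out[i:i + batch] = self._forward(crops[i:i + batch])
        return out

    def predict(self, crops: np.ndarray) -> np.ndarray:
        return self.predict_proba(crops).argmax(axis=1)

    def fit(
        self,
        crops: np.ndarray,
        labels: np.ndarray,
        epochs: int = 12,
        batch: int = 32,
        lr: float = 0.01,
        momentum: float = 0.9,
        seed: int = 0,
        verbose: bool = False,
    ) -> "TinyConvNet":
        x = self._standardize(crops)
        y = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(seed)
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            cur_lr = lr * (0.5 ** (epoch // 4))
            losses = []
            for i in range(0, n, batch):
                idx = order[i:i + batch]
                xb, yb = x[idx], y[idx]
                p = self._forward(xb)
                losses.append(-np.log(p[np.arange(len(yb)), yb] + 1e-12).mean())
                dlogits = p
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                d_fcW = self._flat.T @ dlogits
                d_fcb = dlogits.sum(axis=0)
                dflat = dlogits @ self.fc_W.T
                self.v_fcW = momentum * self.v_fcW - cur_lr * d_fcW
                self.v_fcb = momentum * self.v_fcb - cur_lr * d_fcb
                self.fc_W += self.v_fcW
                self.fc_b += self.v_fcb
                da = dflat.reshape(self._flat_shape)
                for ci in range(len(self.convs) - 1, -1, -1):
                    da = self.convs[ci].backward(da, need_dx=ci > 0)
                    self.convs[ci].step(cur_lr, momentum)
            if verbose:
                print(f"epoch {epoch}: loss {np.mean(losses):.4f}")
        return self

    # -- serialization ------------------------------------------------
    def to_arrays(self) -> dict:
        d = {
            "input_shape": np.array(self.input_shape),
            "n_classes": np.array(self.n_classes),
            "conv_channels": np.array([c.out_c for c in self.convs]),
            "fc_W": self.fc_W,
            "fc_b": self.fc_b,
        }
        for i, c in enumerate(self.convs):
            d[f"conv{i}_W"] = c.W
            d[f"conv{i}_b"] = c.b
        return d

    @classmethod
    def from_arrays(cls, d: dict) -> "TinyConvNet":
        net = cls(
            input_shape=tuple(int(v) for v in d["input_shape"]),
            conv_channels=tuple(int(v) for v in d["conv_channels"]),
            n_classes=int(d["n_classes"]),
        )
        for i, c in enumerate(net.convs):
            c.W = d[f"conv{i}_W"]
            c.b = d[f"conv{i}_b"]
        net.fc_W = d["fc_W"]
        net.fc_b = d["fc_b"]
        return net
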