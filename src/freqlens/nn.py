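"""A minimal convolutional network with explicit numpy backprop.

The analyses in this package need classifiers that expose exact input
gradients (for PGD attacks and composed defenses) while staying small enough
to train in seconds on one CPU. This module provides exactly that: a fixed
two-block architecture

    conv 5x5 (C -> 8) - ReLU - avgpool 2 - conv 5x5 (8 -> 16) - ReLU -
    avgpool 2 - dense -> K classes

with well under 50k parameters, trained by Adam on the cross-entropy loss.
Forward, parameter gradients and input gradients are all hand-derived; the
input gradient is verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .models import ClassifierHandle, softmax

__all__ = ["TinyCNN"]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Patches of a zero-padded batch as a (B, H, W, kh*kw*cin) matrix."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (B, H, W, cin, kh, kw) -> (B, H, W, kh, kw, cin) to match W's layout
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        x.shape[0], x.shape[1], x.shape[2], -1
    )


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded cross-correlation, channels-last. W: (kh, kw, cin, cout)."""
    kh, kw, cin, cout = W.shape
    cols = _im2col(x, kh, kw)
    out = cols.reshape(-1, kh * kw * cin) @ W.reshape(-1, cout)
    return out.reshape(*x.shape[:3], cout) + b


def _conv_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    kh, kw, cin, cout = W.shape
    B, H, Wd, _ = x.shape
    cols = _im2col(x, kh, kw).reshape(-1, kh * kw * cin)
    dflat = dout.reshape(-1, cout)
    dW = (cols.T @ dflat).reshape(W.shape)
    db = dflat.sum(axis=0)
    # Scatter column gradients back through the patch extraction.
    dcols = (dflat @ W.reshape(-1, cout).T).reshape(B, H, Wd, kh, kw, cin)
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((B, H + 2 * ph, Wd + 2 * pw, cin))
    for di in range(kh):
        for dj in range(kw):
            dxp[:, di : di + H, dj : dj + Wd, :] += dcols[:, :, :, di, dj, :]
    dx = dxp[:, ph : ph + H, pw : pw + Wd, :]
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int) -> np.ndarray:
    B, H, W, C = x.shape
    return x.reshape(B, H // p, p, W // p, p, C).mean(axis=(2, 4))


def _pool_backward(dout: np.ndarray, p: int) -> np.ndarray:
    return np.repeat(np.repeat(dout, p, axis=1), p, axis=2) / (p * p)


class TinyCNN(ClassifierHandle):
    """Small trainable CNN satisfying the probe/attack contract.

    Parameters are initialized and training batches are shuffled from a
    single seeded generator, so training is bit-reproducible. ``converged``
    is set to False (with a warning) when the final train accuracy stays
    below 80% — callers are never left with a silently broken model.
    """

    POOL = 2
    KSIZE = 5
    CH1 = 8
    CH2 = 16

    def __init__(self, input_shape: tuple[int, ...], n_classes: int, seed: int = 0):
        if len(input_shape) == 2:
            input_shape = (*input_shape, 1)
        H, W, C = input_shape
        if H % 4 or W % 4:
            raise ValueError("input height/width must be divisible by 4")
        self.input_shape = input_shape if input_shape[2] > 1 else input_shape[:2]
        self._chw = (H, W, C)
        self.n_classes = n_classes
        self.converged = True
        rng = np.random.default_rng(seed)
        k = self.KSIZE
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / (k * k * C)), (k, k, C, self.CH1)),
            "b1": np.zeros(self.CH1),
            "W2": rng.normal(0, np.sqrt(2.0 / (k * k * self.CH1)), (k, k, self.CH1, self.CH2)),
            "b2": np.zeros(self.CH2),
            "W3": rng.normal(
                0, np.sqrt(1.0 / (H // 4 * (W // 4) * self.CH2)),
                (H // 4 * (W // 4) * self.CH2, n_classes),
            ),
            "b3": np.zeros(n_classes),
        }
        self._rng = rng

    # -- forward / backward ------------------------------------------------

    def _as_chw_batch(self, images: np.ndarray) -> np.ndarray:
        images = self._check_batch(images)
        if images.ndim == 3:
            images = images[..., None]
        return images

    def _forward(self, x: np.ndarray) -> dict:
        p = self.params
        a1 = _conv_forward(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1 = _pool_forward(r1, self.POOL)
        a2 = _conv_forward(p1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2 = _pool_forward(r2, self.POOL)
        flat = p2.reshape(len(x), -1)
        scores = flat @ p["W3"] + p["b3"]
        return {"x": x, "a1": a1, "p1": p1, "a2": a2, "p2": p2, "flat": flat, "scores": scores}

    def _backward(self, cache: dict, dscores: np.ndarray, need_param_grads: bool = True):
        p = self.params
        grads = {}
        dflat = dscores @ p["W3"].T
        if need_param_grads:
            grads["W3"] = cache["flat"].T @ dscores
            grads["b3"] = dscores.sum(axis=0)
        dp2 = dflat.reshape(cache["p2"].shape)
        dr2 = _pool_backward(dp2, self.POOL)
        da2 = dr2 * (cache["a2"] > 0)
        dp1, dW2, db2 = _conv_backward(cache["p1"], p["W2"], da2)
        if need_param_grads:
            grads["W2"], grads["b2"] = dW2, db2
        dr1 = _pool_backward(dp1, self.POOL)
        da1 = dr1 * (cache["a1"] > 0)
        dx, dW1, db1 = _conv_backward(cache["x"], p["W1"], da1)
        if need_param_grads:
            grads["W1"], grads["b1"] = dW1, db1
        return dx, grads

    # -- public contract ---------------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        out = []
        x = self._as_chw_batch(images)
        for start in range(0, len(x), 256):
            out.append(softmax(self._forward(x[start : start + 256])["scores"]))
        return np.concatenate(out)

    def loss_gradient(self, images: np.ndarray, targets: np.ndarray) -> np.ndarray:
        images_in = np.asarray(images, dtype=float)
        x = self._as_chw_batch(images)
        targets = np.atleast_1d(np.asarray(targets, dtype=int))
        cache = self._forward(x)
        dscores = softmax(cache["scores"])
        dscores[np.arange(len(x)), targets] -= 1.0
        dx, _ = self._backward(cache, dscores, need_param_grads=False)
        return dx.reshape(images_in.shape)

    # -- training ----------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 10,
        batch_size: int = 64,
        lr: float = 3e-3,
    ) -> "TinyCNN":
        """Adam training on cross-entropy; reproducible given the ctor seed."""
        x = self._as_chw_batch(images)
        y = np.asarray(labels, dtype=int)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(w) for k, w in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(epochs):
            order = self._rng.permutation(len(x))
            for start in range(0, len(x), batch_size):
                idx = order[start : start + batch_size]
                cache = self._forward(x[idx])
                probs = softmax(cache["scores"])
                dscores = probs.copy()
                dscores[np.arange(len(idx)), y[idx]] -= 1.0
                dscores /= len(idx)
                _, grads = self._backward(cache, dscores)
                t += 1
                for k in self.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        train_acc = float((self.predict(images) == y).mean())
        self.train_accuracy = train_acc
        if train_acc < 0.8:
            self.converged = False
            import warnings

            warnings.warn(
                f"TinyCNN training did not converge (train accuracy {train_acc:.2f} < 0.80)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            input_shape=np.array(self._chw),
            n_classes=np.array(self.n_classes),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "TinyCNN":
        data = np.load(path)
        model = cls(tuple(int(v) for v in data["input_shape"]), int(data["n_classes"]))
        for k in model.params:
            model.params[k] = data[k]
        return model
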