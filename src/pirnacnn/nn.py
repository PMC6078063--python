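"""Minimal CNN engine: forward/backward passes, Adam, in float32.

Implements exactly the layer stack the classifier needs — valid 2x2
convolutions, 2x2/stride-2 max pooling with floor division, inverted
dropout, dense layers, softmax cross-entropy — with nothing generic
beyond that.  Convolutions are evaluated as im2col matrix products so
the heavy lifting happens in BLAS; elementwise steps run in place,
since on a single CPU core the training loop is memory-bound, not
flop-bound.

Shapes through the network for the 4x341 input:
    conv1 -> (3, 340, 32), conv2 -> (2, 339, 32),
    pool  -> (1, 169, 32), flatten -> 5408, dense -> 512, out -> 2.

All randomness (Glorot initialization, dropout masks) flows from seeded
``numpy.random.Generator`` instances, so training is reproducible.
"""

from __future__ import annotations

import ctypes
import sys

import numpy as np

# Batch-sized intermediates are several MB, which glibc serves via
# mmap/munmap by default: every batch then pays page faults on first
# touch.  Keeping large blocks on the heap lets the allocator recycle
# them across batches (~20% of the step time).
if sys.platform.startswith("linux"):  # pragma: no branch
    try:
        _libc = ctypes.CDLL("libc.so.6")
        _libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        _libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except OSError:  # pragma: no cover
        pass

_EPS = 1e-12


def conv_output_shape(shape: tuple[int, int], kernel: tuple[int, int]) -> tuple[int, int]:
    """Spatial shape after a valid (unpadded) convolution."""
    return (shape[0] - kernel[0] + 1, shape[1] - kernel[1] + 1)


def pool_output_shape(shape: tuple[int, int], pool: tuple[int, int]) -> tuple[int, int]:
    """Spatial shape after max pooling with stride = pool size (floor)."""
    return (shape[0] // pool[0], shape[1] // pool[1])


def _patches_2x2(x: np.ndarray) -> np.ndarray:
    """im2col for a 2x2 kernel: (N,H,W,C) -> (N,H-1,W-1,4C).

    Patch channel order is (di=0,dj=0), (0,1), (1,0), (1,1), matching
    a row-major flatten of a (2,2,C,F) weight tensor.
    """
    return np.concatenate(
        (x[:, :-1, :-1, :], x[:, :-1, 1:, :], x[:, 1:, :-1, :], x[:, 1:, 1:, :]),
        axis=3,
    )


def _scatter_patches_2x2(dpatches: np.ndarray, in_shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_patches_2x2` (col2im by accumulation)."""
    n, h, w, c = in_shape
    dx = np.zeros(in_shape, dtype=dpatches.dtype)
    dx[:, :-1, :-1, :] += dpatches[..., 0 * c : 1 * c]
    dx[:, :-1, 1:, :] += dpatches[..., 1 * c : 2 * c]
    dx[:, 1:, :-1, :] += dpatches[..., 2 * c : 3 * c]
    dx[:, 1:, 1:, :] += dpatches[..., 3 * c : 4 * c]
    return dx


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + _EPS), axis=1)))


class Network:
    """The fixed conv-conv-pool-dense-softmax classifier."""

    def __init__(self, arch, seed: int):
        from pirnacnn.model import CNNArchitecture  # avoid import cycle

        self.arch: CNNArchitecture = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = arch.filters
        c_in = arch.input_shape[2]
        h, w = arch.input_shape[:2]
        kh, kw = arch.kernel
        # weights in matmul-ready layout; (kh*kw*C, F) rows follow the
        # patch order of _patches_2x2
        self.params: dict[str, np.ndarray] = {}
        self.params["W1"] = _glorot(rng, (kh * kw * c_in, f), kh * kw * c_in, kh * kw * f)
        self.params["b1"] = np.zeros(f, dtype=np.float32)
        self.params["W2"] = _glorot(rng, (kh * kw * f, f), kh * kw * f, kh * kw * f)
        self.params["b2"] = np.zeros(f, dtype=np.float32)
        shape = conv_output_shape(conv_output_shape((h, w), arch.kernel), arch.kernel)
        pooled = pool_output_shape(shape, arch.pool)
        self.flat_dim = pooled[0] * pooled[1] * f
        self.params["Wd"] = _glorot(rng, (self.flat_dim, arch.dense_units), self.flat_dim, arch.dense_units)
        self.params["bd"] = np.zeros(arch.dense_units, dtype=np.float32)
        self.params["Wo"] = _glorot(rng, (arch.dense_units, arch.n_classes), arch.dense_units, arch.n_classes)
        self.params["bo"] = np.zeros(arch.n_classes, dtype=np.float32)

    # -- forward -----------------------------------------------------------

    def _conv_relu(self, x: np.ndarray, w_key: str, b_key: str) -> tuple[np.ndarray, np.ndarray]:
        """Valid 2x2 convolution + rectifier; returns (patches, activation)."""
        patches = _patches_2x2(x)
        n, h, w, pc = patches.shape
        act = patches.reshape(-1, pc) @ self.params[w_key]
        act += self.params[b_key]
        np.maximum(act, 0.0, out=act)
        return patches, act.reshape(n, h, w, -1)

    def _pool(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ph, pw = self.arch.pool
        n, h, w, c = a.shape
        hh, ww = h // ph, w // pw
        blocks = a[:, : hh * ph, : ww * pw, :].reshape(n, hh, ph, ww, pw, c)
        pooled = blocks.max(axis=(2, 4))
        return pooled, blocks

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the network; returns (probabilities, cache for backward).

        With ``train=True`` dropout is applied using ``drop_rng``; at
        inference dropout is disabled and the pass is deterministic.
        Rectified activations double as their own gradient masks
        (act > 0), so pre-activation values are not kept.
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        p1, a1 = self._conv_relu(x, "W1", "b1")
        p2, a2 = self._conv_relu(a1, "W2", "b2")
        pooled, blocks = self._pool(a2)
        flat = pooled.reshape(x.shape[0], -1)

        cache: dict = {"p1": p1, "a1": a1, "p2": p2, "a2": a2,
                       "blocks": blocks, "pooled": pooled}
        if train:
            keep1 = 1.0 - self.arch.dropout_after_pool
            mask1 = (drop_rng.random(flat.shape, dtype=np.float32) < keep1).astype(np.float32)
            mask1 /= keep1
            flat = flat * mask1
            cache["mask1"] = mask1
        cache["flat"] = flat

        hid = flat @ self.params["Wd"]
        hid += self.params["bd"]
        np.maximum(hid, 0.0, out=hid)
        cache["hid"] = hid
        if train:
            keep2 = 1.0 - self.arch.dropout_after_dense
            mask2 = (drop_rng.random(hid.shape, dtype=np.float32) < keep2).astype(np.float32)
            mask2 /= keep2
            hid = hid * mask2
            cache["mask2"] = mask2
        cache["hid_dropped"] = hid

        logits = hid @ self.params["Wo"]
        logits += self.params["bo"]
        probs = softmax(logits)
        cache["probs"] = probs
        return probs, cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter.

        Consumes the cache (intermediates are modified in place).
        """
        n = onehot.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = cache["probs"] - onehot
        dlogits /= n

        grads["Wo"] = cache["hid_dropped"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dhid = dlogits @ self.params["Wo"].T
        if "mask2" in cache:
            dhid *= cache["mask2"]
        dhid *= cache["hid"] > 0

        grads["Wd"] = cache["flat"].T @ dhid
        grads["bd"] = dhid.sum(axis=0)
        dflat = dhid @ self.params["Wd"].T
        if "mask1" in cache:
            dflat *= cache["mask1"]

        # max-pool: gradient splits evenly among tied maxima in a block
        dpooled = dflat.reshape(cache["pooled"].shape)
        blocks = cache["blocks"]
        ties = blocks == cache["pooled"][:, :, None, :, None, :]
        tie_counts = ties.sum(axis=(2, 4), keepdims=True, dtype=np.float32)
        dblocks = ties * (dpooled[:, :, None, :, None, :] / tie_counts)
        a2 = cache["a2"]
        da2 = np.zeros_like(a2)
        nb, hh, ph, ww, pw, c = dblocks.shape
        da2[:, : hh * ph, : ww * pw, :] = dblocks.reshape(nb, hh * ph, ww * pw, c)

        da2 *= a2 > 0
        pc2 = cache["p2"].shape[-1]
        dz2 = da2.reshape(-1, da2.shape[-1])
        grads["W2"] = cache["p2"].reshape(-1, pc2).T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dp2 = (dz2 @ self.params["W2"].T).reshape(cache["p2"].shape)
        da1 = _scatter_patches_2x2(dp2, cache["a1"].shape)

        da1 *= cache["a1"] > 0
        pc1 = cache["p1"].shape[-1]
        dz1 = da1.reshape(-1, da1.shape[-1])
        grads["W1"] = cache["p1"].reshape(-1, pc1).T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities with dropout disabled; deterministic."""
        x = np.asarray(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self.forward(x[start : start + batch_size], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=np.float32).copy() for k, v in params.items()}


class Adam:
    """Adam at the usual framework defaults (lr 1e-3, betas .9/.999).

    Uses the lr-rescaled update form (bias correction folded into the
    step size) and a preallocated scratch buffer per parameter: the
    optimizer state is as large as the model, so temporaries matter.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self._scratch = {k: np.empty_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        step_size = np.float32(
            self.lr * np.sqrt(1.0 - self.beta2 ** self.t) / (1.0 - self.beta1 ** self.t)
        )
        for key, g in grads.items():
            m, v, buf = self.m[key], self.v[key], self._scratch[key]
            m *= self.beta1
            np.multiply(g, np.float32(1.0 - self.beta1), out=buf)
            m += buf
            v *= self.beta2
            np.multiply(g, g, out=buf)
            buf *= np.float32(1.0 - self.beta2)
            v += buf
            np.sqrt(v, out=buf)
            buf += np.float32(self.eps)
            np.divide(m, buf, out=buf)
            buf *= step_size
            params[key] -= buf
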