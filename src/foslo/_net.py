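"""A compact 1-D convolutional classifier in plain numpy.

The network treats a feature vector of length ``L`` as a one-channel
signal: a stack of valid-padding conv+ReLU blocks, global average pooling,
one dense ReLU layer, and a softmax output.  Training is full-batch Adam
on the mean cross-entropy, seeded He initialization, a fixed step budget —
every run of the same (architecture, data, seed, epochs) is bit-identical.

All gradients are derived by hand; tests check them against central finite
differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallConvNet", "cross_entropy"]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallConvNet:
    """conv blocks -> global average pool -> dense -> softmax."""

    def __init__(self, n_features: int, n_blocks: int, n_filters: int,
                 kernel: int, dense_units: int, n_classes: int = 2, seed: int = 0):
        if n_features - n_blocks * (kernel - 1) < 1:
            raise ValueError(
                f"{n_blocks} conv blocks with kernel {kernel} exhaust "
                f"{n_features} input features"
            )
        self.n_features = n_features
        self.n_blocks = n_blocks
        self.n_filters = n_filters
        self.kernel = kernel
        self.dense_units = dense_units
        self.n_classes = n_classes

        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = 1
        for _ in range(n_blocks):
            fan_in = c_in * kernel
            self.conv_w.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), (n_filters, c_in, kernel))
            )
            self.conv_b.append(np.zeros(n_filters))
            c_in = n_filters
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / n_filters), (n_filters, dense_units))
        self.b1 = np.zeros(dense_units)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / dense_units), (dense_units, n_classes))
        self.b2 = np.zeros(n_classes)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.w1, self.b1, self.w2, self.b2]

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ------------------------------------------------
    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        # x: (B, Cin, L) -> (B, L-K+1, Cin*K), contiguous for BLAS matmul
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        b, c, l_out, _ = windows.shape
        return np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
            b, l_out, c * k
        )

    @staticmethod
    def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # x: (B, Cin, L); w: (Cout, Cin, K) -> (B, Cout, L-K+1)
        cols = SmallConvNet._im2col(x, w.shape[2])
        out = cols @ w.reshape(w.shape[0], -1).T  # (B, L_out, Cout)
        return out.transpose(0, 2, 1) + b[None, :, None]

    def _forward(self, x2d: np.ndarray):
        x = x2d[:, None, :]  # (B, 1, L)
        cache = []
        h = x
        for w, b in zip(self.conv_w, self.conv_b):
            pre = self._conv_forward(h, w, b)
            post = np.maximum(pre, 0.0)
            cache.append((h, pre))
            h = post
        pooled = h.mean(axis=2)  # (B, C)
        d_pre = pooled @ self.w1 + self.b1
        d_post = np.maximum(d_pre, 0.0)
        logits = d_post @ self.w2 + self.b2
        probs = _softmax(logits)
        return probs, (cache, h, pooled, d_pre, d_post)

    def predict_proba(self, x2d: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(x2d, dtype=float))
        return probs

    def predict(self, x2d: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x2d), axis=1)

    def loss(self, x2d: np.ndarray, labels: np.ndarray) -> float:
        return cross_entropy(self.predict_proba(x2d), labels)

    def _gradients(self, x2d: np.ndarray, labels: np.ndarray):
        n = len(labels)
        probs, (cache, h_last, pooled, d_pre, d_post) = self._forward(x2d)
        d_logits = probs.copy()
        d_logits[np.arange(n), labels] -= 1.0
        d_logits /= n

        g_w2 = d_post.T @ d_logits
        g_b2 = d_logits.sum(axis=0)
        d_dpost = d_logits @ self.w2.T
        d_dpre = d_dpost * (d_pre > 0.0)
        g_w1 = pooled.T @ d_dpre
        g_b1 = d_dpre.sum(axis=0)
        d_pooled = d_dpre @ self.w1.T

        length = h_last.shape[2]
        d_h = np.repeat(d_pooled[:, :, None], length, axis=2) / length
        g_conv_w: list[np.ndarray] = [None] * self.n_blocks  # type: ignore[list-item]
        g_conv_b: list[np.ndarray] = [None] * self.n_blocks  # type: ignore[list-item]
        for layer in range(self.n_blocks - 1, -1, -1):
            x_in, pre = cache[layer]
            d_pre_conv = d_h * (pre > 0.0)
            k = self.kernel
            cols = self._im2col(x_in, k)  # (B, L_out, Cin*K)
            c_out = d_pre_conv.shape[1]
            flat_d = d_pre_conv.transpose(1, 0, 2).reshape(c_out, -1)  # (Cout, B*L_out)
            flat_x = cols.reshape(-1, cols.shape[2])  # (B*L_out, Cin*K)
            g_conv_w[layer] = (flat_d @ flat_x).reshape(self.conv_w[layer].shape)
            g_conv_b[layer] = d_pre_conv.sum(axis=(0, 2))
            if layer > 0:
                # full correlation of d_pre_conv with the flipped kernels
                w_mat = self.conv_w[layer].reshape(c_out, -1)  # (Cout, Cin*K)
                d_cols = d_pre_conv.transpose(0, 2, 1) @ w_mat  # (B, L_out, Cin*K)
                b_n, c_in, length = x_in.shape
                l_out = d_pre_conv.shape[2]
                d_x = np.zeros_like(x_in)
                d_cols = d_cols.reshape(b_n, l_out, c_in, k)
                for off in range(k):
                    d_x[:, :, off:off + l_out] += d_cols[:, :, :, off].transpose(0, 2, 1)
                d_h = d_x
        grads = [*g_conv_w, *g_conv_b, g_w1, g_b1, g_w2, g_b2]
        return cross_entropy(probs, labels), grads

    # -- training ----------------------------------------------------------
    def fit(self, x2d: np.ndarray, labels: np.ndarray, learning_rate: float,
            epochs: int) -> float:
        """Full-batch Adam for a fixed number of steps; returns final loss."""
        x2d = np.asarray(x2d, dtype=float)
        labels = np.asarray(labels, dtype=int)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        loss = np.inf
        for step in range(1, epochs + 1):
            loss, grads = self._gradients(x2d, labels)
            for idx, (p, g) in enumerate(zip(params, grads)):
                m[idx] = beta1 * m[idx] + (1 - beta1) * g
                v[idx] = beta2 * v[idx] + (1 - beta2) * g * g
                m_hat = m[idx] / (1 - beta1**step)
                v_hat = v[idx] / (1 - beta2**step)
                p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        return float(loss)
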