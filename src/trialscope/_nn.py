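"""A compact 1-D convolutional text classifier in numpy.

Architecture: learned word embeddings -> single convolution over token
windows -> ReLU -> max-over-time pooling -> logistic output. Optional extra
dense features (e.g. a publication-type indicator) are concatenated to the
pooled vector before the output layer. Trained with Adam on binary
cross-entropy; fully deterministic for a given seed.

Deliberately small: it is sized for desk-scale corpora of templated
abstracts, not for production biomedical text.
"""

from __future__ import annotations

import re

import numpy as np

_WORD_RE = re.compile(r"[a-z0-9]+")

PAD, UNK = 0, 1


def tokenize_simple(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


class TextCNN:
    def __init__(
        self,
        embed_dim: int = 16,
        n_filters: int = 32,
        window: int = 3,
        max_len: int = 80,
        max_vocab: int = 4000,
        epochs: int = 10,
        batch_size: int = 64,
        lr: float = 2e-3,
        n_extra: int = 0,
        seed: int = 0,
    ):
        self.embed_dim = embed_dim
        self.n_filters = n_filters
        self.window = window
        self.max_len = max_len
        self.max_vocab = max_vocab
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_extra = n_extra
        self.seed = seed
        self.vocab_: dict[str, int] | None = None

    # -- data prep ---------------------------------------------------------

    def _build_vocab(self, texts: list[str]) -> None:
        counts: dict[str, int] = {}
        for t in texts:
            for w in tokenize_simple(t):
                counts[w] = counts.get(w, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: self.max_vocab]
        self.vocab_ = {w: i + 2 for i, (w, _) in enumerate(ranked)}

    def _encode(self, texts: list[str]) -> np.ndarray:
        assert self.vocab_ is not None
        X = np.full((len(texts), self.max_len), PAD, dtype=np.int32)
        for r, t in enumerate(texts):
            toks = tokenize_simple(t)[: self.max_len]
            for c, w in enumerate(toks):
                X[r, c] = self.vocab_.get(w, UNK)
        return X

    # -- forward/backward --------------------------------------------------

    def _forward(self, X: np.ndarray, extra: np.ndarray):
        B, L = X.shape
        w, d, f = self.window, self.embed_dim, self.n_filters
        T = L - w + 1
        emb = self.E[X]  # (B, L, d)
        # im2col over token windows
        windows = np.lib.stride_tricks.sliding_window_view(emb, w, axis=1)  # (B, T, d, w)
        windows = windows.transpose(0, 1, 3, 2).reshape(B, T, w * d)
        pre = windows @ self.W + self.b  # (B, T, f)
        act = np.maximum(pre, 0.0)
        tmax = act.argmax(axis=1)  # (B, f)
        pooled = np.take_along_axis(act, tmax[:, None, :], axis=1)[:, 0, :]  # (B, f)
        h = np.concatenate([pooled, extra], axis=1) if self.n_extra else pooled
        logits = h @ self.u + self.c
        probs = 1.0 / (1.0 + np.exp(-logits))
        cache = (X, windows, pre, tmax, h)
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, windows, pre, tmax, h = cache
        B, T, _ = windows.shape
        f = self.n_filters
        dlogits = (probs - y) / len(y)
        grads = {
            "u": h.T @ dlogits,
            "c": np.array(dlogits.sum()),
        }
        dh = np.outer(dlogits, self.u)
        dpool = dh[:, :f]
        dact = np.zeros((B, T, f))
        np.put_along_axis(dact, tmax[:, None, :], dpool[:, None, :], axis=1)
        dpre = dact * (pre > 0)
        grads["W"] = windows.reshape(B * T, -1).T @ dpre.reshape(B * T, f)
        grads["b"] = dpre.sum(axis=(0, 1))
        dwindows = dpre @ self.W.T  # (B, T, w*d)
        demb = np.zeros((B, X.shape[1], self.embed_dim))
        dwin = dwindows.reshape(B, T, self.window, self.embed_dim)
        for k in range(self.window):
            demb[:, k : k + T, :] += dwin[:, :, k, :]
        dE = np.zeros_like(self.E)
        np.add.at(dE, X.reshape(-1), demb.reshape(-1, self.embed_dim))
        dE[PAD] = 0.0
        grads["E"] = dE
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, texts: list[str], y, extra=None) -> "TextCNN":
        rng = np.random.default_rng(self.seed)
        y = np.asarray(y, dtype=float)
        if extra is None:
            extra = np.zeros((len(texts), self.n_extra))
        extra = np.asarray(extra, dtype=float)
        self._build_vocab(texts)
        X = self._encode(texts)
        V = len(self.vocab_) + 2
        w, d, f = self.window, self.embed_dim, self.n_filters
        self.E = rng.normal(0, 0.1, size=(V, d))
        self.E[PAD] = 0.0
        self.W = rng.normal(0, 0.1, size=(w * d, f))
        self.b = np.zeros(f)
        self.u = rng.normal(0, 0.1, size=f + self.n_extra)
        self.c = np.array(0.0)

        params = ("E", "W", "b", "u", "c")
        m = {p: np.zeros_like(getattr(self, p)) for p in params}
        v = {p: np.zeros_like(getattr(self, p)) for p in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(len(texts))
            for start in range(0, len(texts), self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self._forward(X[idx], extra[idx])
                grads = self._backward(probs, y[idx], cache)
                step += 1
                for p in params:
                    g = grads[p]
                    m[p] = beta1 * m[p] + (1 - beta1) * g
                    v[p] = beta2 * v[p] + (1 - beta2) * g * g
                    mhat = m[p] / (1 - beta1**step)
                    vhat = v[p] / (1 - beta2**step)
                    setattr(self, p, getattr(self, p) - self.lr * mhat / (np.sqrt(vhat) + eps))
        return self

    def predict_proba(self, texts: list[str], extra=None) -> np.ndarray:
        if extra is None:
            extra = np.zeros((len(texts), self.n_extra))
        extra = np.asarray(extra, dtype=float)
        X = self._encode(texts)
        out = np.empty(len(texts))
        for start in range(0, len(texts), 256):
            sl = slice(start, start + 256)
            out[sl] = self._forward(X[sl], extra[sl])[0]
        return out
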