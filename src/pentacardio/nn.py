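"""Minimal numpy transformer encoder for sequence classification.

Forward and backward passes are written explicitly (no autograd); the
gradients are verified against central finite differences in the test
suite.  Architecture: linear input projection -> sinusoidal positional
encoding -> pre-norm transformer encoder layers (multi-head self-attention
+ ReLU feed-forward) -> final layer norm -> mean pooling over time ->
linear classifier, trained with softmax cross-entropy and AdamW.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sinusoidal_positions(n_pos: int, d: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def _layer_norm_forward(x, gamma, beta):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def _layer_norm_backward(dy, cache):
    xhat, inv, gamma = cache
    d = xhat.shape[-1]
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    dx = inv / d * (
        d * dxhat - dxhat.sum(-1, keepdims=True) - xhat * (dxhat * xhat).sum(-1, keepdims=True)
    )
    return dx, dgamma, dbeta


class TransformerClassifier:
    """Sequence classifier over (batch, seq_len, n_features) inputs."""

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        d_model: int = 64,
        n_layers: int = 2,
        n_heads: int = 2,
        d_ff: int = 128,
        max_len: int = 512,
        seed: int = 0,
        dtype=np.float32,
    ):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_features = n_features
        self.n_classes = n_classes
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.dtype = np.dtype(dtype)
        self.pos = sinusoidal_positions(max_len, d_model).astype(self.dtype)
        rng = np.random.default_rng(seed)
        p = {}

        def lin(name, fan_in, fan_out):
            p[f"{name}.W"] = rng.normal(
                0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out)
            ).astype(self.dtype)
            p[f"{name}.b"] = np.zeros(fan_out, self.dtype)

        lin("in", n_features, d_model)
        for l in range(n_layers):
            for nm in ("q", "k", "v", "o"):
                lin(f"l{l}.{nm}", d_model, d_model)
            lin(f"l{l}.ff1", d_model, d_ff)
            lin(f"l{l}.ff2", d_ff, d_model)
            for ln in ("ln1", "ln2"):
                p[f"l{l}.{ln}.g"] = np.ones(d_model, self.dtype)
                p[f"l{l}.{ln}.b"] = np.zeros(d_model, self.dtype)
        p["lnf.g"] = np.ones(d_model, self.dtype)
        p["lnf.b"] = np.zeros(d_model, self.dtype)
        lin("cls", d_model, n_classes)
        self.params = p

    # -------------------------------------------------------------- forward

    def _attention_forward(self, a, l, p):
        B, L, D = a.shape
        H, dh = self.n_heads, self.d_model // self.n_heads

        def heads(x):
            return x.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q = heads(a @ p[f"l{l}.q.W"] + p[f"l{l}.q.b"])
        k = heads(a @ p[f"l{l}.k.W"] + p[f"l{l}.k.b"])
        v = heads(a @ p[f"l{l}.v.W"] + p[f"l{l}.v.b"])
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        A = softmax(scores, axis=-1)
        o = A @ v  # (B,H,L,dh)
        oc = o.transpose(0, 2, 1, 3).reshape(B, L, D)
        out = oc @ p[f"l{l}.o.W"] + p[f"l{l}.o.b"]
        return out, (a, q, k, v, A, oc)

    def _attention_backward(self, dout, cache, l, p, grads):
        a, q, k, v, A, oc = cache
        B, L, D = a.shape
        H, dh = self.n_heads, self.d_model // self.n_heads
        grads[f"l{l}.o.W"] += oc.reshape(-1, D).T @ dout.reshape(-1, D)
        grads[f"l{l}.o.b"] += dout.sum((0, 1))
        doc = dout @ p[f"l{l}.o.W"].T
        do = doc.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        dA = do @ v.transpose(0, 1, 3, 2)
        dv = A.transpose(0, 1, 3, 2) @ do
        dS = A * (dA - (dA * A).sum(-1, keepdims=True))
        dS /= np.sqrt(dh)
        dq = dS @ k
        dk = dS.transpose(0, 1, 3, 2) @ q

        da = np.zeros_like(a)
        for nm, dx in (("q", dq), ("k", dk), ("v", dv)):
            dflat = dx.transpose(0, 2, 1, 3).reshape(B * L, D)
            grads[f"l{l}.{nm}.W"] += a.reshape(-1, D).T @ dflat
            grads[f"l{l}.{nm}.b"] += dflat.sum(0)
            da += (dflat @ p[f"l{l}.{nm}.W"].T).reshape(B, L, D)
        return da

    def forward(self, X: np.ndarray, pos_start: int = 0):
        """Logits for X of shape (B, L, n_features); returns (logits, cache).

        ``pos_start`` offsets the positional encoding so that a cropped
        subsequence keeps the positions it had in the full sequence.
        """
        p = self.params
        X = np.asarray(X, self.dtype)
        B, L, _ = X.shape
        if pos_start + L > self.pos.shape[0]:
            self.pos = sinusoidal_positions(pos_start + L, self.d_model).astype(self.dtype)
        h = X @ p["in.W"] + p["in.b"] + self.pos[pos_start : pos_start + L]
        caches = []
        for l in range(self.n_layers):
            a, c_ln1 = _layer_norm_forward(h, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            attn, c_att = self._attention_forward(a, l, p)
            h1 = h + attn
            b, c_ln2 = _layer_norm_forward(h1, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            z1 = b @ p[f"l{l}.ff1.W"] + p[f"l{l}.ff1.b"]
            r = np.maximum(z1, 0.0)
            f = r @ p[f"l{l}.ff2.W"] + p[f"l{l}.ff2.b"]
            h = h1 + f
            caches.append((c_ln1, c_att, c_ln2, b, z1, r))
        hf, c_lnf = _layer_norm_forward(h, p["lnf.g"], p["lnf.b"])
        pooled = hf.mean(axis=1)
        logits = pooled @ p["cls.W"] + p["cls.b"]
        return logits, (X, caches, c_lnf, hf, pooled)

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        X, caches, c_lnf, hf, pooled = cache
        B, L, _ = X.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["cls.W"] += pooled.T @ dlogits
        grads["cls.b"] += dlogits.sum(0)
        dpooled = dlogits @ p["cls.W"].T
        dhf = np.repeat(dpooled[:, None, :], L, axis=1) / L
        dh, dg, db = _layer_norm_backward(dhf, c_lnf)
        grads["lnf.g"] += dg
        grads["lnf.b"] += db
        for l in range(self.n_layers - 1, -1, -1):
            c_ln1, c_att, c_ln2, b, z1, r = caches[l]
            D = self.d_model
            df = dh
            grads[f"l{l}.ff2.W"] += r.reshape(-1, self.d_ff).T @ df.reshape(-1, D)
            grads[f"l{l}.ff2.b"] += df.sum((0, 1))
            dr = df @ p[f"l{l}.ff2.W"].T
            dz1 = dr * (z1 > 0)
            grads[f"l{l}.ff1.W"] += b.reshape(-1, D).T @ dz1.reshape(-1, self.d_ff)
            grads[f"l{l}.ff1.b"] += dz1.sum((0, 1))
            db_ = dz1 @ p[f"l{l}.ff1.W"].T
            dh1_ln, dg, dbeta = _layer_norm_backward(db_, c_ln2)
            grads[f"l{l}.ln2.g"] += dg
            grads[f"l{l}.ln2.b"] += dbeta
            dh1 = dh + dh1_ln
            da = self._attention_backward(dh1, c_att, l, p, grads)
            dh_ln, dg, dbeta = _layer_norm_backward(da, c_ln1)
            grads[f"l{l}.ln1.g"] += dg
            grads[f"l{l}.ln1.b"] += dbeta
            dh = dh1 + dh_ln
        dflat = dh.reshape(-1, self.d_model)
        grads["in.W"] += X.reshape(-1, self.n_features).T @ dflat
        grads["in.b"] += dflat.sum(0)
        return grads

    # -------------------------------------------------------------- training

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, pos_start: int = 0):
        logits, cache = self.forward(X, pos_start)
        B = X.shape[0]
        probs = softmax(logits)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        return loss, self.backward(dlogits, cache)

    def loss(self, X: np.ndarray, y: np.ndarray, pos_start: int = 0) -> float:
        logits, _ = self.forward(X, pos_start)
        probs = softmax(logits)
        return float(-np.mean(np.log(probs[np.arange(X.shape[0]), y] + 1e-300)))

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits, _ = self.forward(X[i : i + batch_size])
            out.append(softmax(logits))
        return np.vstack(out)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], self.dtype).copy()


class AdamW:
    """AdamW with decoupled weight decay (decay on matrices only)."""

    def __init__(self, params: dict, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            upd = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.wd and p.ndim >= 2:
                p -= self.lr * self.wd * p
            p -= self.lr * upd
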