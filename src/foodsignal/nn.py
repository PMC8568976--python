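"""Minimal transformer encoder in numpy with analytic gradients.

This is the desk-scale shared encoder behind the dual-task model: piece
embeddings + learned positions, a stack of pre-norm self-attention blocks,
and a final layer norm.  Forward passes cache intermediates; ``backward``
returns exact parameter gradients (verified against numerical
differentiation in the test suite).  Everything runs in float64 on CPU —
the corpora this package trains on are small by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEG_INF = -1e9
_LN_EPS = 1e-5


@dataclass
class TransformerSpec:
    """Architecture hyperparameters of the tiny encoder."""

    vocab_size: int
    hidden: int = 64
    layers: int = 2
    heads: int = 2
    ffn: int = 0  # 0 -> 2 * hidden
    max_length: int = 48

    def __post_init__(self) -> None:
        if self.hidden < 8:
            raise ValueError("hidden size must be >= 8")
        if self.max_length < 8:
            raise ValueError("max_length must be >= 8")
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if self.ffn <= 0:
            self.ffn = 2 * self.hidden


def _ln_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _linear(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    y = x.reshape(-1, x.shape[-1]) @ w
    y = y.reshape(*x.shape[:-1], w.shape[1])
    return y + b if b is not None else y


def _linear_backward(dy: np.ndarray, x: np.ndarray, w: np.ndarray):
    dy2 = dy.reshape(-1, dy.shape[-1])
    x2 = x.reshape(-1, x.shape[-1])
    dw = x2.T @ dy2
    db = dy2.sum(0)
    dx = (dy2 @ w.T).reshape(x.shape)
    return dx, dw, db


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TinyTransformer:
    """Pre-norm multi-head self-attention encoder with explicit backprop."""

    def __init__(self, spec: TransformerSpec, rng: np.random.Generator):
        self.spec = spec
        h, f = spec.hidden, spec.ffn
        p: dict[str, np.ndarray] = {
            "emb": rng.normal(0.0, 0.02, (spec.vocab_size, h)),
            "pos": rng.normal(0.0, 0.02, (spec.max_length, h)),
            "lnf_g": np.ones(h),
            "lnf_b": np.zeros(h),
        }
        for l in range(spec.layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{l}_{name}"] = rng.normal(0.0, 0.02, (h, h))
            p[f"l{l}_ln1_g"] = np.ones(h)
            p[f"l{l}_ln1_b"] = np.zeros(h)
            p[f"l{l}_ln2_g"] = np.ones(h)
            p[f"l{l}_ln2_b"] = np.zeros(h)
            p[f"l{l}_w1"] = rng.normal(0.0, 0.02, (h, f))
            p[f"l{l}_b1"] = np.zeros(f)
            p[f"l{l}_w2"] = rng.normal(0.0, 0.02, (f, h))
            p[f"l{l}_b2"] = np.zeros(h)
        self.params = p

    # -- forward ----------------------------------------------------------

    def forward(self, ids: np.ndarray, mask: np.ndarray):
        """ids, mask: (B, T) -> final hidden states (B, T, H) + cache."""
        p, spec = self.params, self.spec
        nh = spec.heads
        dh = spec.hidden // nh
        B, T = ids.shape

        x = p["emb"][ids] + p["pos"][:T]
        key_bias = (_NEG_INF * (1.0 - mask))[:, None, None, :]  # (B,1,1,T)
        cache: dict = {"ids": ids, "mask": mask, "layers": []}

        def split(z):  # (B,T,H) -> (B,nh,T,dh)
            return z.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        for l in range(spec.layers):
            lc: dict = {"x_in": x}
            xn, lc["ln1"] = _ln_forward(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            lc["xn1"] = xn
            q = split(_linear(xn, p[f"l{l}_wq"]))
            k = split(_linear(xn, p[f"l{l}_wk"]))
            v = split(_linear(xn, p[f"l{l}_wv"]))
            s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            a = softmax(s)
            ctx = (a @ v).transpose(0, 2, 1, 3).reshape(B, T, spec.hidden)
            lc.update(q=q, k=k, v=v, a=a, ctx=ctx)
            x = x + _linear(ctx, p[f"l{l}_wo"])

            lc["x_mid"] = x
            xn2, lc["ln2"] = _ln_forward(x, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            lc["xn2"] = xn2
            h1 = _linear(xn2, p[f"l{l}_w1"], p[f"l{l}_b1"])
            lc["h1"] = h1
            x = x + _linear(np.maximum(h1, 0.0), p[f"l{l}_w2"], p[f"l{l}_b2"])
            cache["layers"].append(lc)

        out, cache["lnf"] = _ln_forward(x, p["lnf_g"], p["lnf_b"])
        return out, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dout: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt all encoder parameters, given the
        gradient wrt the forward output."""
        p, spec = self.params, self.spec
        nh = spec.heads
        dh = spec.hidden // nh
        ids = cache["ids"]
        B, T = ids.shape
        g: dict[str, np.ndarray] = {}

        dx, g["lnf_g"], g["lnf_b"] = _ln_backward(dout, cache["lnf"])

        def merge(z):  # (B,nh,T,dh) -> (B,T,H)
            return z.transpose(0, 2, 1, 3).reshape(B, T, spec.hidden)

        for l in reversed(range(spec.layers)):
            lc = cache["layers"][l]
            # FFN block: x_out = x_mid + relu(ln2(x_mid) @ w1 + b1) @ w2 + b2
            relu = np.maximum(lc["h1"], 0.0)
            da, g[f"l{l}_w2"], g[f"l{l}_b2"] = _linear_backward(dx, relu, p[f"l{l}_w2"])
            dh1 = da * (lc["h1"] > 0)
            dxn2, g[f"l{l}_w1"], g[f"l{l}_b1"] = _linear_backward(
                dh1, lc["xn2"], p[f"l{l}_w1"]
            )
            dmid, g[f"l{l}_ln2_g"], g[f"l{l}_ln2_b"] = _ln_backward(dxn2, lc["ln2"])
            dx = dx + dmid

            # attention block: x_mid = x_in + (A V) Wo
            dctx, g[f"l{l}_wo"], _dbo = _linear_backward(dx, lc["ctx"], p[f"l{l}_wo"])
            dctx = dctx.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            a, q, k, v = lc["a"], lc["q"], lc["k"], lc["v"]
            da_att = dctx @ v.transpose(0, 1, 3, 2)
            dv = a.transpose(0, 1, 3, 2) @ dctx
            ds = a * (da_att - (da_att * a).sum(-1, keepdims=True))
            ds = ds / np.sqrt(dh)
            dq = ds @ k
            dk = ds.transpose(0, 1, 3, 2) @ q
            dxn = np.zeros_like(lc["xn1"])
            for name, dz in (("wq", dq), ("wk", dk), ("wv", dv)):
                dpart, g[f"l{l}_{name}"], _ = _linear_backward(
                    merge(dz), lc["xn1"], p[f"l{l}_{name}"]
                )
                dxn += dpart
            din, g[f"l{l}_ln1_g"], g[f"l{l}_ln1_b"] = _ln_backward(dxn, lc["ln1"])
            dx = dx + din

        g["pos"] = dx.sum(0)[:T]
        if T < spec.max_length:
            g["pos"] = np.vstack(
                [g["pos"], np.zeros((spec.max_length - T, spec.hidden))]
            )
        g["emb"] = np.zeros_like(p["emb"])
        np.add.at(g["emb"], ids, dx)
        return g


class Adam:
    """Plain Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
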