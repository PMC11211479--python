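"""Minimal numpy transformer with hand-written backpropagation.

A compact decoder-only, pre-LayerNorm transformer with causal
sliding-window ("local") self-attention and a next-token cross-entropy
objective.  Gradients are derived by hand and verified against finite
differences in the test suite; everything runs on numpy arrays so the
model is fully deterministic on one machine for a fixed seed.

Sequences are right-padded; the causal mask keeps padding out of every
real position's receptive field and padded positions carry zero loss
weight.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

Params = Dict[str, np.ndarray]

_NEG = -1e30  # mask bias; softmax of -1e30 underflows to exactly 0


def init_params(
    vocab_size: int,
    hidden: int,
    n_layers: int,
    n_heads: int,
    max_len: int,
    rng: np.random.Generator,
) -> Params:
    if hidden % n_heads != 0:
        raise ValueError("hidden size must be divisible by n_heads")
    std = 0.02
    p: Params = {
        "emb": rng.normal(0, std, (vocab_size, hidden)),
        "pos": rng.normal(0, std, (max_len, hidden)),
        "lnf_g": np.ones(hidden),
        "lnf_b": np.zeros(hidden),
        "out_w": rng.normal(0, std, (hidden, vocab_size)),
        "out_b": np.zeros(vocab_size),
    }
    for l in range(n_layers):
        p[f"l{l}.ln1_g"] = np.ones(hidden)
        p[f"l{l}.ln1_b"] = np.zeros(hidden)
        p[f"l{l}.qkv_w"] = rng.normal(0, std, (hidden, 3 * hidden))
        p[f"l{l}.qkv_b"] = np.zeros(3 * hidden)
        p[f"l{l}.att_w"] = rng.normal(0, std / math.sqrt(2 * n_layers), (hidden, hidden))
        p[f"l{l}.att_b"] = np.zeros(hidden)
        p[f"l{l}.ln2_g"] = np.ones(hidden)
        p[f"l{l}.ln2_b"] = np.zeros(hidden)
        p[f"l{l}.fc_w"] = rng.normal(0, std, (hidden, 4 * hidden))
        p[f"l{l}.fc_b"] = np.zeros(4 * hidden)
        p[f"l{l}.proj_w"] = rng.normal(0, std / math.sqrt(2 * n_layers), (4 * hidden, hidden))
        p[f"l{l}.proj_b"] = np.zeros(hidden)
    return p


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_bwd(dy: np.ndarray, cache, g: np.ndarray):
    xhat, inv = cache
    d = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    del d
    return dx, dg, db


def _mask_bias(T: int, window: int) -> np.ndarray:
    """(T, T) additive bias: position t may attend to (t-window, t]."""
    i = np.arange(T)[:, None]
    j = np.arange(T)[None, :]
    allowed = (j <= i) & (j > i - window)
    return np.where(allowed, 0.0, _NEG)


class TinyCausalLM:
    """Decoder-only local-attention transformer over code tokens."""

    def __init__(
        self,
        vocab_size: int,
        hidden: int = 64,
        n_layers: int = 2,
        n_heads: int = 4,
        max_len: int = 64,
        window: int = 64,
        seed: int = 0,
        params: Params | None = None,
    ):
        self.vocab_size = vocab_size
        self.hidden = hidden
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.max_len = max_len
        self.window = window
        self.params = (
            params
            if params is not None
            else init_params(
                vocab_size, hidden, n_layers, n_heads, max_len, np.random.default_rng(seed)
            )
        )

    # -- forward ------------------------------------------------------------

    def _forward(self, ids: np.ndarray, collect: bool):
        """Run the trunk; returns final hidden states and (optionally) caches."""
        p = self.params
        B, T = ids.shape
        H, d = self.n_heads, self.hidden
        dh = d // H
        scale = 1.0 / math.sqrt(dh)
        bias = _mask_bias(T, self.window)

        x = p["emb"][ids] + p["pos"][:T]
        caches = []
        for l in range(self.n_layers):
            pre = f"l{l}."
            x1, ln1c = _layernorm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            qkv = x1 @ p[pre + "qkv_w"] + p[pre + "qkv_b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            S = np.einsum("bhtd,bhsd->bhts", q, k, optimize=True) * scale + bias
            S -= S.max(axis=-1, keepdims=True)
            A = np.exp(S)
            A /= A.sum(axis=-1, keepdims=True)
            O = np.einsum("bhts,bhsd->bhtd", A, v, optimize=True)
            Om = O.transpose(0, 2, 1, 3).reshape(B, T, d)
            att = Om @ p[pre + "att_w"] + p[pre + "att_b"]
            x_mid = x + att
            x2, ln2c = _layernorm(x_mid, p[pre + "ln2_g"], p[pre + "ln2_b"])
            hpre = x2 @ p[pre + "fc_w"] + p[pre + "fc_b"]
            h = np.maximum(hpre, 0.0)
            m = h @ p[pre + "proj_w"] + p[pre + "proj_b"]
            x_out = x_mid + m
            if collect:
                caches.append(
                    dict(x=x, x1=x1, ln1c=ln1c, q=q, k=k, v=v, A=A, Om=Om,
                         x_mid=x_mid, x2=x2, ln2c=ln2c, h=h)
                )
            x = x_out
        xf, lnfc = _layernorm(x, p["lnf_g"], p["lnf_b"])
        return x, xf, lnfc, caches

    def hidden_states(self, ids: np.ndarray) -> np.ndarray:
        """Final-LayerNorm hidden states, shape (B, T, hidden)."""
        _, xf, _, _ = self._forward(ids, collect=False)
        return xf

    def loss(self, ids: np.ndarray, lengths: np.ndarray) -> float:
        """Mean next-token cross-entropy (nats) over valid positions."""
        loss, _ = self._loss_impl(ids, lengths, want_grads=False)
        return loss

    def loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray):
        return self._loss_impl(ids, lengths, want_grads=True)

    # -- loss + backward -----------------------------------------------------

    def _loss_impl(self, ids: np.ndarray, lengths: np.ndarray, want_grads: bool):
        p = self.params
        B, T = ids.shape
        H, d = self.n_heads, self.hidden
        dh = d // H
        scale = 1.0 / math.sqrt(dh)

        x_last, xf, lnfc, caches = self._forward(ids, collect=want_grads)
        logits = xf @ p["out_w"] + p["out_b"]  # (B, T, V)

        # position t predicts token t+1; valid while t+1 < length
        wmask = np.zeros((B, T))
        for b in range(B):
            wmask[b, : max(0, int(lengths[b]) - 1)] = 1.0
        n_valid = wmask.sum()
        if n_valid == 0:
            raise ValueError("no supervised positions in batch")
        targets = np.zeros((B, T), dtype=np.int64)
        targets[:, :-1] = ids[:, 1:]

        zmax = logits.max(axis=-1, keepdims=True)
        ez = np.exp(logits - zmax)
        sm = ez / ez.sum(axis=-1, keepdims=True)
        logp = np.log(
            np.take_along_axis(sm, targets[..., None], axis=-1)[..., 0] + 1e-300
        )
        loss = float(-(logp * wmask).sum() / n_valid)
        if not want_grads:
            return loss, None
        if not math.isfinite(loss):
            raise FloatingPointError("non-finite pretraining loss")

        dlogits = sm.copy()
        np.put_along_axis(
            dlogits, targets[..., None],
            np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0, axis=-1,
        )
        dlogits *= (wmask / n_valid)[..., None]

        grads: Params = {}
        grads["out_w"] = np.einsum("btd,btv->dv", xf, dlogits, optimize=True)
        grads["out_b"] = dlogits.sum(axis=(0, 1))
        dxf = dlogits @ p["out_w"].T
        dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_bwd(dxf, lnfc, p["lnf_g"])

        for l in reversed(range(self.n_layers)):
            pre = f"l{l}."
            c = caches[l]
            # MLP branch
            dm = dx  # residual: x_out = x_mid + m
            grads[pre + "proj_w"] = np.einsum("bth,btd->hd", c["h"], dm, optimize=True)
            grads[pre + "proj_b"] = dm.sum(axis=(0, 1))
            dh_ = dm @ p[pre + "proj_w"].T
            dh_ = dh_ * (c["h"] > 0)
            grads[pre + "fc_w"] = np.einsum("btd,bth->dh", c["x2"], dh_, optimize=True)
            grads[pre + "fc_b"] = dh_.sum(axis=(0, 1))
            dx2 = dh_ @ p[pre + "fc_w"].T
            dx_mid_ln, grads[pre + "ln2_g"], grads[pre + "ln2_b"] = _layernorm_bwd(
                dx2, c["ln2c"], p[pre + "ln2_g"]
            )
            dx_mid = dx + dx_mid_ln
            # attention branch: x_mid = x + att
            datt = dx_mid
            grads[pre + "att_w"] = np.einsum("btd,bte->de", c["Om"], datt, optimize=True)
            grads[pre + "att_b"] = datt.sum(axis=(0, 1))
            dOm = datt @ p[pre + "att_w"].T
            dO = dOm.reshape(dOm.shape[0], dOm.shape[1], H, dh).transpose(0, 2, 1, 3)
            A, q, k, v = c["A"], c["q"], c["k"], c["v"]
            dA = np.einsum("bhtd,bhsd->bhts", dO, v, optimize=True)
            dv = np.einsum("bhts,bhtd->bhsd", A, dO, optimize=True)
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dq = np.einsum("bhts,bhsd->bhtd", dS, k, optimize=True) * scale
            dk = np.einsum("bhts,bhtd->bhsd", dS, q, optimize=True) * scale
            B_, T_ = dOm.shape[0], dOm.shape[1]
            dqkv = np.concatenate(
                [
                    dq.transpose(0, 2, 1, 3).reshape(B_, T_, d),
                    dk.transpose(0, 2, 1, 3).reshape(B_, T_, d),
                    dv.transpose(0, 2, 1, 3).reshape(B_, T_, d),
                ],
                axis=-1,
            )
            grads[pre + "qkv_w"] = np.einsum("btd,bte->de", c["x1"], dqkv, optimize=True)
            grads[pre + "qkv_b"] = dqkv.sum(axis=(0, 1))
            dx1 = dqkv @ p[pre + "qkv_w"].T
            dx_ln, grads[pre + "ln1_g"], grads[pre + "ln1_b"] = _layernorm_bwd(
                dx1, c["ln1c"], p[pre + "ln1_g"]
            )
            dx = dx_mid + dx_ln

        dpos = np.zeros_like(p["pos"])
        dpos[: dx.shape[1]] += dx.sum(axis=0)
        grads["pos"] = dpos
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, ids.reshape(-1), dx.reshape(-1, d))
        grads["emb"] = demb
        return loss, grads


class Adam:
    def __init__(self, params: Params, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for key, g in grads.items():
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def pad_batch(seqs: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad integer sequences; returns (ids, lengths)."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    T = int(lengths.max())
    ids = np.zeros((len(seqs), T), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
    return ids, lengths
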