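"""Bidirectional transformer encoder in NumPy with hand-written backprop.

Pre-LayerNorm architecture: token + position embeddings, ``n_layers``
blocks of multi-head self-attention and a ReLU feed-forward network with
residual connections, a final LayerNorm, and a tied-free linear output
head over the vocabulary for the masked-symbol objective.  Padding
positions are excluded from attention.  Gradients are exact (verified
against finite differences in the test suite) and training uses Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LN_EPS = 1e-5
_NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    ``full_scale`` matches the published model (256-symbol capacity,
    512-dimensional embeddings); ``test_scale`` is a small preset for
    desk-scale training.  ``embed_dim`` must be divisible by ``n_heads``.
    """

    max_len: int = 256
    embed_dim: int = 512
    n_layers: int = 6
    n_heads: int = 8
    ff_dim: int = 2048
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @staticmethod
    def full_scale(seed: int = 0) -> "EncoderConfig":
        return EncoderConfig(seed=seed)

    @staticmethod
    def test_scale(seed: int = 0, dropout: float = 0.0) -> "EncoderConfig":
        return EncoderConfig(max_len=256, embed_dim=64, n_layers=2, n_heads=2,
                             ff_dim=128, dropout=dropout, seed=seed)

    def to_dict(self) -> dict:
        return {
            "max_len": self.max_len, "embed_dim": self.embed_dim,
            "n_layers": self.n_layers, "n_heads": self.n_heads,
            "ff_dim": self.ff_dim, "dropout": self.dropout, "seed": self.seed,
        }


def _layernorm_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


class TransformerEncoder:
    """Parameter container plus forward/backward passes.

    ``forward`` maps padded id matrices to final hidden states (B, T, D);
    ``backward`` takes the gradient w.r.t. those states, so both the
    masked-LM head and supervised task heads can drive training.
    """

    def __init__(self, vocab_size: int, cfg: EncoderConfig,
                 params: dict[str, np.ndarray] | None = None) -> None:
        self.vocab_size = vocab_size
        self.cfg = cfg
        self.params = params if params is not None else self._init_params()

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        D, F = cfg.embed_dim, cfg.ff_dim

        def lin(n_in, n_out):
            return rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))

        p: dict[str, np.ndarray] = {
            "tok_emb": rng.normal(0.0, 0.02, size=(self.vocab_size, D)),
            "pos_emb": rng.normal(0.0, 0.02, size=(cfg.max_len, D)),
            "lnf_g": np.ones(D), "lnf_b": np.zeros(D),
            "out_w": lin(D, self.vocab_size), "out_b": np.zeros(self.vocab_size),
        }
        for l in range(cfg.n_layers):
            p[f"l{l}_ln1_g"] = np.ones(D)
            p[f"l{l}_ln1_b"] = np.zeros(D)
            p[f"l{l}_ln2_g"] = np.ones(D)
            p[f"l{l}_ln2_b"] = np.zeros(D)
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{l}_{name}"] = lin(D, D)
                p[f"l{l}_b{name[1]}"] = np.zeros(D)
            p[f"l{l}_ff1_w"] = lin(D, F)
            p[f"l{l}_ff1_b"] = np.zeros(F)
            p[f"l{l}_ff2_w"] = lin(F, D)
            p[f"l{l}_ff2_b"] = np.zeros(D)
        return p

    # -- forward -----------------------------------------------------------

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray,
                train: bool = False, dropout_rng: np.random.Generator | None = None):
        """Hidden states for padded id matrix ``ids`` (B, T).

        ``pad_mask`` is True at real positions.  Returns (hidden, cache).
        Dropout is applied only when ``train`` and cfg.dropout > 0.
        """
        cfg, p = self.cfg, self.params
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh = D // H
        drop = cfg.dropout if train else 0.0

        def dropout_mask(shape):
            if drop == 0.0:
                return None
            return (dropout_rng.random(shape) >= drop) / (1.0 - drop)

        h = p["tok_emb"][ids] + p["pos_emb"][:T]
        key_bias = np.where(pad_mask, 0.0, _NEG_INF)[:, None, None, :]  # (B,1,1,T)
        caches = []
        for l in range(cfg.n_layers):
            a, ln1_cache = _layernorm_forward(h, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            q = a @ p[f"l{l}_wq"] + p[f"l{l}_bq"]
            k = a @ p[f"l{l}_wk"] + p[f"l{l}_bk"]
            v = a @ p[f"l{l}_wv"] + p[f"l{l}_bv"]
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(-1, keepdims=True)
            ctx = att @ vh
            ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
            attn_out = ctx2 @ p[f"l{l}_wo"] + p[f"l{l}_bo"]
            m1 = dropout_mask(attn_out.shape)
            if m1 is not None:
                attn_out = attn_out * m1
            h1 = h + attn_out

            b2, ln2_cache = _layernorm_forward(h1, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            ff_pre = b2 @ p[f"l{l}_ff1_w"] + p[f"l{l}_ff1_b"]
            ff_act = np.maximum(ff_pre, 0.0)
            ff_out = ff_act @ p[f"l{l}_ff2_w"] + p[f"l{l}_ff2_b"]
            m2 = dropout_mask(ff_out.shape)
            if m2 is not None:
                ff_out = ff_out * m2
            h = h1 + ff_out
            caches.append((a, ln1_cache, qh, kh, vh, att, ctx2, m1, h1,
                           b2, ln2_cache, ff_pre, ff_act, m2))

        hf, lnf_cache = _layernorm_forward(h, p["lnf_g"], p["lnf_b"])
        cache = (ids, pad_mask, caches, lnf_cache)
        return hf, cache

    def logits(self, hidden: np.ndarray) -> np.ndarray:
        return hidden @ self.params["out_w"] + self.params["out_b"]

    # -- backward ----------------------------------------------------------

    def backward(self, d_hidden: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of all encoder parameters given d(loss)/d(hidden)."""
        cfg, p = self.cfg, self.params
        ids, pad_mask, caches, lnf_cache = cache
        B, T = ids.shape
        H, D = cfg.n_heads, cfg.embed_dim
        dh = D // H
        grads: dict[str, np.ndarray] = {}

        dhid, grads["lnf_g"], grads["lnf_b"] = _layernorm_backward(d_hidden, lnf_cache)

        for l in reversed(range(cfg.n_layers)):
            (a, ln1_cache, qh, kh, vh, att, ctx2, m1, h1,
             b2, ln2_cache, ff_pre, ff_act, m2) = caches[l]
            # feed-forward block
            dff_out = dhid if m2 is None else dhid * m2
            grads[f"l{l}_ff2_w"] = ff_act.reshape(-1, cfg.ff_dim).T @ dff_out.reshape(-1, D)
            grads[f"l{l}_ff2_b"] = dff_out.sum((0, 1))
            dff_act = dff_out @ p[f"l{l}_ff2_w"].T
            dff_pre = dff_act * (ff_pre > 0)
            grads[f"l{l}_ff1_w"] = b2.reshape(-1, D).T @ dff_pre.reshape(-1, cfg.ff_dim)
            grads[f"l{l}_ff1_b"] = dff_pre.sum((0, 1))
            db2 = dff_pre @ p[f"l{l}_ff1_w"].T
            dh1_ln, grads[f"l{l}_ln2_g"], grads[f"l{l}_ln2_b"] = _layernorm_backward(db2, ln2_cache)
            dh1 = dhid + dh1_ln
            # attention block
            dattn_out = dh1 if m1 is None else dh1 * m1
            grads[f"l{l}_wo"] = ctx2.reshape(-1, D).T @ dattn_out.reshape(-1, D)
            grads[f"l{l}_bo"] = dattn_out.sum((0, 1))
            dctx2 = dattn_out @ p[f"l{l}_wo"].T
            dctx = dctx2.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            datt = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ dctx
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            dqh = dscores @ kh / np.sqrt(dh)
            dkh = dscores.transpose(0, 1, 3, 2) @ qh / np.sqrt(dh)
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, D)
            a_flat = a.reshape(-1, D)
            grads[f"l{l}_wq"] = a_flat.T @ dq.reshape(-1, D)
            grads[f"l{l}_bq"] = dq.sum((0, 1))
            grads[f"l{l}_wk"] = a_flat.T @ dk.reshape(-1, D)
            grads[f"l{l}_bk"] = dk.sum((0, 1))
            grads[f"l{l}_wv"] = a_flat.T @ dv.reshape(-1, D)
            grads[f"l{l}_bv"] = dv.sum((0, 1))
            da = dq @ p[f"l{l}_wq"].T + dk @ p[f"l{l}_wk"].T + dv @ p[f"l{l}_wv"].T
            dh_ln, grads[f"l{l}_ln1_g"], grads[f"l{l}_ln1_b"] = _layernorm_backward(da, ln1_cache)
            dhid = dh1 + dh_ln

        grads["pos_emb"] = np.zeros_like(p["pos_emb"])
        grads["pos_emb"][:T] = dhid.sum(0)
        grads["tok_emb"] = np.zeros_like(p["tok_emb"])
        np.add.at(grads["tok_emb"], ids, dhid)
        return grads


def masked_lm_loss(encoder: TransformerEncoder, ids: np.ndarray, pad_mask: np.ndarray,
                   target_ids: np.ndarray, target_mask: np.ndarray,
                   train: bool = False, dropout_rng: np.random.Generator | None = None):
    """Mean cross-entropy at selected positions, with parameter gradients.

    ``target_mask`` is True at positions whose original symbol must be
    recovered.  Returns (loss, grads, n_targets); grads is None when no
    position is selected.
    """
    hidden, cache = encoder.forward(ids, pad_mask, train=train, dropout_rng=dropout_rng)
    logits = encoder.logits(hidden)
    n_targets = int(target_mask.sum())
    if n_targets == 0:
        return 0.0, None, 0
    shifted = logits - logits.max(-1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(-1, keepdims=True))
    log_probs = shifted - log_z
    b_idx, t_idx = np.nonzero(target_mask)
    tgt = target_ids[b_idx, t_idx]
    loss = -log_probs[b_idx, t_idx, tgt].mean()

    probs = np.exp(log_probs)
    dlogits = np.zeros_like(logits)
    dlogits[b_idx, t_idx] = probs[b_idx, t_idx]
    dlogits[b_idx, t_idx, tgt] -= 1.0
    dlogits /= n_targets
    grads = {"out_w": hidden.reshape(-1, encoder.cfg.embed_dim).T
                      @ dlogits.reshape(-1, encoder.vocab_size),
             "out_b": dlogits.sum((0, 1))}
    d_hidden = dlogits @ encoder.params["out_w"].T
    grads.update(encoder.backward(d_hidden, cache))
    return float(loss), grads, n_targets


class Adam:
    """Standard Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
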