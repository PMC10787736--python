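"""NumPy building blocks for the Siamese character model.

Implements the forward and backward passes of the twin-tower encoder:

* a per-position embedding pipeline (vocab 28 -> dense 130 -> dense 130 ->
  dense 30, ReLU hidden activations, padding positions zeroed),
* a bidirectional LSTM over the padded character sequence whose final
  hidden states (one per direction) are concatenated into the tower
  summary vector,
* a cosine-distance merge clipped to [0, 1], evaluated in the
  numerically exact "chord" form ``CD = ||u - w||^2 / 2`` on the
  L2-normalized summaries ``u, w`` (algebraically identical to
  ``1 - cos`` but returns exactly 0 for identical inputs), with
  ``d = min(CD, 1)``,
* the contrastive loss and its gradient,
* Adam parameter updates.

Weight sharing is structural: both sides of every pair run through one
parameter set in a single stacked batch, so the towers cannot diverge.
All tensors are float32 by default; float64 is supported for gradient
checking. Sequences are processed up to the longest non-padding length in
the batch — masked steps carry the recurrent state unchanged, so skipping
the all-padding tail does not alter any output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

ParamDict = dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh form is overflow-safe for large |x|
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_params(
    vocab_size: int,
    embed_hidden: int,
    embed_dim: int,
    lstm_units: int,
    rng: np.random.Generator,
    dtype=np.float32,
) -> ParamDict:
    """Initialize all trainable parameters (Glorot weights, forget-gate bias 1)."""
    H = lstm_units
    params: ParamDict = {
        "emb_W1": _glorot(rng, vocab_size, embed_hidden, dtype),
        "emb_b1": np.zeros(embed_hidden, dtype=dtype),
        "emb_W2": _glorot(rng, embed_hidden, embed_hidden, dtype),
        "emb_b2": np.zeros(embed_hidden, dtype=dtype),
        "emb_W3": _glorot(rng, embed_hidden, embed_dim, dtype),
        "emb_b3": np.zeros(embed_dim, dtype=dtype),
    }
    for d in ("fwd", "bwd"):
        params[f"{d}_Wx"] = _glorot(rng, embed_dim, 4 * H, dtype)
        params[f"{d}_Wh"] = _glorot(rng, H, 4 * H, dtype)
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0  # forget gate bias
        params[f"{d}_b"] = b
    return params


# ---------------------------------------------------------------------------
# Embedding pipeline


def _embed_forward(params: ParamDict, X: np.ndarray, mask: np.ndarray):
    """Per-position MLP: one-hot gather -> 130 -> 130 -> 30, padding zeroed."""
    A1 = params["emb_W1"][X] + params["emb_b1"]  # (N, T, h1)
    R1 = np.maximum(A1, 0.0)
    A2 = R1 @ params["emb_W2"] + params["emb_b2"]
    R2 = np.maximum(A2, 0.0)
    E = R2 @ params["emb_W3"] + params["emb_b3"]
    E = E * mask[..., None]
    cache = (X, mask, A1, R1, A2, R2)
    return E, cache


def _embed_backward(params: ParamDict, cache, dE: np.ndarray, grads: ParamDict) -> None:
    X, mask, A1, R1, A2, R2 = cache
    dE = dE * mask[..., None]
    n_flat = dE.shape[0] * dE.shape[1]
    dE2 = dE.reshape(n_flat, -1)
    R2f = R2.reshape(n_flat, -1)
    grads["emb_W3"] += R2f.T @ dE2
    grads["emb_b3"] += dE2.sum(axis=0)
    dR2 = (dE2 @ params["emb_W3"].T) * (A2.reshape(n_flat, -1) > 0)
    R1f = R1.reshape(n_flat, -1)
    grads["emb_W2"] += R1f.T @ dR2
    grads["emb_b2"] += dR2.sum(axis=0)
    dR1 = (dR2 @ params["emb_W2"].T) * (A1.reshape(n_flat, -1) > 0)
    np.add.at(grads["emb_W1"], X.reshape(-1), dR1)
    grads["emb_b1"] += dR1.sum(axis=0)


# ---------------------------------------------------------------------------
# LSTM


def _lstm_forward(
    params: ParamDict, prefix: str, E: np.ndarray, mask: np.ndarray,
    pooling: str = "final",
):
    """Run one direction over (N, T, emb); returns the tower summary.

    ``pooling="final"`` returns the hidden state at each sequence's last
    real character (padded steps carry ``h`` and ``c`` unchanged);
    ``pooling="mean"`` returns the masked mean of the hidden states over
    the real characters.
    """
    N, T, _ = E.shape
    H = params[f"{prefix}_Wh"].shape[0]
    dtype = E.dtype
    Xp = E.reshape(N * T, -1) @ params[f"{prefix}_Wx"]
    Xp = (Xp + params[f"{prefix}_b"]).reshape(N, T, 4 * H)
    Wh = params[f"{prefix}_Wh"]
    h = np.zeros((N, H), dtype=dtype)
    c = np.zeros((N, H), dtype=dtype)
    steps = []
    if pooling == "mean":
        hsum = np.zeros((N, H), dtype=dtype)
    for t in range(T):
        z = Xp[:, t] + h @ Wh
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t : t + 1]
        steps.append((i, f, g, o, c, tc, h, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        if pooling == "mean":
            hsum += m * h
    lengths = mask.sum(axis=1, keepdims=True).astype(dtype)
    out = hsum / lengths if pooling == "mean" else h
    cache = (E, mask, Xp, steps, H, pooling, lengths)
    return out, cache


def _lstm_backward(
    params: ParamDict, prefix: str, cache, dout: np.ndarray, grads: ParamDict
) -> np.ndarray:
    """Backprop through time for one direction; returns dE."""
    E, mask, Xp, steps, H, pooling, lengths = cache
    N, T, _ = E.shape
    Wh = params[f"{prefix}_Wh"]
    dtype = E.dtype
    if pooling == "mean":
        dh = np.zeros((N, H), dtype=dtype)
        dmean = (dout / lengths).astype(dtype)
    else:
        dh = dout.astype(dtype)
        dmean = None
    dc = np.zeros_like(dh)
    dXp = np.zeros_like(Xp)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev, m = steps[t]
        if pooling == "mean":
            # the post-update h at step t fed the running sum (masked)
            dh = dh + m * dmean
        dh_new = m * dh
        dh_prev_carry = (1.0 - m) * dh
        dc_new = m * dc
        dc_prev_carry = (1.0 - m) * dc
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dc = dc_new * f + dc_prev_carry
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dXp[:, t] = dz
        grads[f"{prefix}_Wh"] += h_prev.T @ dz
        dh = dz @ Wh.T + dh_prev_carry
    dXp_flat = dXp.reshape(N * T, 4 * H)
    grads[f"{prefix}_Wx"] += E.reshape(N * T, -1).T @ dXp_flat
    grads[f"{prefix}_b"] += dXp_flat.sum(axis=0)
    dE = (dXp_flat @ params[f"{prefix}_Wx"].T).reshape(E.shape)
    return dE


# ---------------------------------------------------------------------------
# Encoder = embedding + BiLSTM


def encoder_forward(
    params: ParamDict,
    X: np.ndarray,
    *,
    pooling: str = "final",
    dropout: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    dtype=np.float32,
):
    """Map integer sequences (N, T) to tower summary vectors (N, 2H).

    ``dropout`` (training only) applies inverted dropout to the embedded
    characters before the recurrent towers.
    """
    mask = (X > 0).astype(dtype)
    E, emb_cache = _embed_forward(params, X, mask)
    drop_mask = None
    if dropout > 0.0 and dropout_rng is not None:
        keep = 1.0 - dropout
        drop_mask = (dropout_rng.uniform(size=E.shape) < keep).astype(dtype) / keep
        E = E * drop_mask
    h_f, cache_f = _lstm_forward(params, "fwd", E, mask, pooling)
    h_b, cache_b = _lstm_forward(params, "bwd", E[:, ::-1], mask[:, ::-1], pooling)
    v = np.concatenate([h_f, h_b], axis=1)
    return v, (emb_cache, cache_f, cache_b, drop_mask)


def encoder_backward(params: ParamDict, cache, dv: np.ndarray, grads: ParamDict) -> None:
    emb_cache, cache_f, cache_b, drop_mask = cache
    H = dv.shape[1] // 2
    dE = _lstm_backward(params, "fwd", cache_f, dv[:, :H], grads)
    dE_rev = _lstm_backward(params, "bwd", cache_b, dv[:, H:], grads)
    dE = dE + dE_rev[:, ::-1]
    if drop_mask is not None:
        dE = dE * drop_mask
    _embed_backward(params, emb_cache, dE, grads)


# ---------------------------------------------------------------------------
# Merge + loss


def contrastive_loss_from_vectors(
    va: np.ndarray, vb: np.ndarray, labels: np.ndarray, margin: float,
    loss_space: str = "output",
) -> float:
    """Mean contrastive loss without gradients (for evaluation passes)."""
    if loss_space == "euclidean":
        diff = va - vb
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        hinge = np.maximum(0.0, margin - dist)
        return float(np.where(labels == 0, dist * dist, hinge * hinge).mean())
    d = pair_distances_from_vectors(va, vb)
    hinge = np.maximum(0.0, margin - d)
    return float(np.where(labels == 0, d * d, hinge * hinge).mean())


def pair_distances_from_vectors(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Model output distance: cosine distance clipped to [0, 1].

    Computed in the exact chord form ``CD = ||u - w||^2 / 2`` on the
    normalized summaries (identically 0 for identical inputs, exactly
    symmetric), then clipped: ``d = min(CD, 1)``. The clip maps the
    obtuse half of the sphere to the maximal distance, so a margin of 1
    asks cross-group pairs to be *orthogonal or further* — attainable for
    any number of groups up to the embedding dimension — while the 0.5
    threshold separates within-60-degrees from beyond-60-degrees.
    """
    ua = va / np.linalg.norm(va, axis=1, keepdims=True)
    ub = vb / np.linalg.norm(vb, axis=1, keepdims=True)
    diff = ua - ub
    return np.minimum(0.5 * np.einsum("ij,ij->i", diff, diff), 1.0)


def contrastive_forward_backward(
    va: np.ndarray, vb: np.ndarray, labels: np.ndarray, margin: float,
    loss_space: str = "output",
):
    """Per-batch contrastive loss over tower summary vectors.

    Returns ``(mean loss, d, dva, dvb)`` where ``d`` are the model's
    output distances (rescaled cosine). Label 0 pulls the pair together;
    label 1 pushes it beyond the margin.

    ``loss_space`` selects which distance the loss acts on:

    * ``"output"`` — the rescaled cosine distance ``d`` itself
      (loss ``d^2`` / ``max(0, margin - d)^2``);
    * ``"euclidean"`` — the raw Euclidean distance between tower outputs
      ``||va - vb||`` (loss ``||.||^2`` / ``max(0, margin - ||.||)^2``),
      leaving the cosine merge as the inference-time distance. Euclidean
      space is unbounded, so many groups can satisfy the margin
      simultaneously, which a spherical geometry cannot.
    """
    N = va.shape[0]
    na = np.linalg.norm(va, axis=1, keepdims=True)
    nb = np.linalg.norm(vb, axis=1, keepdims=True)
    ua = va / na
    ub = vb / nb
    udiff = ua - ub
    d_raw = 0.5 * np.einsum("ij,ij->i", udiff, udiff)
    d = np.minimum(d_raw, 1.0)
    if loss_space == "euclidean":
        diff = va - vb
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        hinge = np.maximum(0.0, margin - dist)
        loss_vec = np.where(labels == 0, dist * dist, hinge * hinge)
        loss = float(loss_vec.mean())
        # dL/ddist, mean over batch; ddist/dva = diff/dist
        ddist = np.where(labels == 0, 2.0 * dist, -2.0 * hinge) / N
        safe = np.maximum(dist, 1e-12)
        dva = (ddist / safe)[:, None].astype(va.dtype) * diff
        dvb = -dva
        return loss, d, dva, dvb
    hinge = np.maximum(0.0, margin - d)
    loss_vec = np.where(labels == 0, d * d, hinge * hinge)
    loss = float(loss_vec.mean())
    # dL/dd, mean over batch; the clip gates the gradient
    dd = np.where(labels == 0, 2.0 * d, -2.0 * hinge) * (d_raw < 1.0) / N
    dd = dd.astype(va.dtype)
    # d = 0.5 ||ua - ub||^2 (pre-clip)  =>  dd/dua = (ua - ub)
    dua = dd[:, None] * udiff
    dub = -dua
    # backprop through L2 normalization: du/dv = (I - u u^T)/||v||
    dva = (dua - ua * np.einsum("ij,ij->i", ua, dua)[:, None]) / na
    dvb = (dub - ub * np.einsum("ij,ij->i", ub, dub)[:, None]) / nb
    return loss, d, dva, dvb


def loss_and_grads(
    params: ParamDict,
    Xa: np.ndarray,
    Xb: np.ndarray,
    labels: np.ndarray,
    margin: float,
    *,
    pooling: str = "final",
    loss_space: str = "output",
    dropout: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    dtype=np.float32,
):
    """Full forward/backward for one minibatch of encoded pairs.

    Both sides are stacked into a single batch through the shared encoder,
    which is what makes the towers Siamese.
    """
    N = Xa.shape[0]
    X = np.concatenate([Xa, Xb], axis=0)
    v, cache = encoder_forward(
        params, X, pooling=pooling, dropout=dropout, dropout_rng=dropout_rng,
        dtype=dtype,
    )
    va, vb = v[:N], v[N:]
    loss, d, dva, dvb = contrastive_forward_backward(va, vb, labels, margin, loss_space)
    grads: ParamDict = {k: np.zeros_like(p) for k, p in params.items()}
    dv = np.concatenate([dva, dvb], axis=0)
    encoder_backward(params, cache, dv, grads)
    return loss, d, grads


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, params: ParamDict, grads: ParamDict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
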