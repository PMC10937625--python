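"""Mapper-network layers: message passing, reaction cross-attention, and the
atom-mapping classifier head.

All functions operate on autograd :class:`~atommap.nn.autograd.Tensor`
objects and a flat parameter dictionary, so the same code serves training
(gradients) and inference (plain forward).  Shapes follow the merged-graph
convention: one big block-diagonal graph per batch with an additive mask
keeping attention within each reaction.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .autograd import Tensor, concat, gather_rows, layer_norm, softmax

__all__ = [
    "init_parameters",
    "mpnn_encode",
    "cross_attention_block",
    "cross_attend",
    "classifier_scores",
]

NEG_INF = -1e9


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(
    rng: np.random.Generator,
    atom_dim: int,
    bond_dim: int,
    hidden_dim: int,
    mpnn_layers: int,
    attention_blocks: int,
) -> dict[str, Tensor]:
    """Glorot-initialized trainable parameters as a flat name->Tensor dict.

    One MPNN stack is shared by the reactant and product sides (both sides
    are plain molecules; the asymmetry of the model lives in the
    cross-attention, which only updates product features).
    """
    d = hidden_dim
    p: dict[str, np.ndarray] = {}
    for t in range(mpnn_layers):
        din = atom_dim if t == 0 else d
        p[f"mpnn{t}_Wmsg"] = _glorot(rng, din + bond_dim, d)
        p[f"mpnn{t}_bmsg"] = np.zeros((1, d))
        p[f"mpnn{t}_Wself"] = _glorot(rng, din, d)
        p[f"mpnn{t}_bself"] = np.zeros((1, d))
    for b in range(attention_blocks):
        for w in ("Wq", "Wk", "Wv", "Wg", "Wf1", "Wf2"):
            p[f"att{b}_{w}"] = _glorot(rng, d, d)
        for bias in ("bg", "bf1", "bf2", "ln1_b", "ln2_b"):
            p[f"att{b}_{bias}"] = np.zeros((1, d))
        for gamma in ("ln1_g", "ln2_g"):
            p[f"att{b}_{gamma}"] = np.ones((1, d))
    p["clf_Wq"] = _glorot(rng, d, d)
    p["clf_Wk"] = _glorot(rng, d, d)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def _scatter_matrix(n_atoms: int, src: np.ndarray) -> np.ndarray:
    S = np.zeros((n_atoms, len(src)))
    if len(src):
        S[src, np.arange(len(src))] = 1.0
    return S


def mpnn_encode(
    params: dict[str, Tensor],
    atom_features: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    bond_features: np.ndarray,
    mpnn_layers: int,
) -> Tensor:
    """Run the message-passing stack over one (merged) molecular graph.

    Per layer, each atom receives the sum over incident bonds of a learned
    transform of ``[neighbor features, bond features]`` and combines it with
    its own transform through a ReLU.  Isolated atoms simply pass through
    their own transform: their embedding cannot depend on other molecules.
    """
    h = Tensor(atom_features)
    n_atoms = atom_features.shape[0]
    S = _scatter_matrix(n_atoms, src)
    bonds = Tensor(bond_features)
    for t in range(mpnn_layers):
        own = h @ params[f"mpnn{t}_Wself"] + params[f"mpnn{t}_bself"]
        if len(src):
            neighbor = gather_rows(h, dst)
            msg = concat([neighbor, bonds], axis=1) @ params[f"mpnn{t}_Wmsg"]
            msg = msg + params[f"mpnn{t}_bmsg"]
            agg = Tensor(S) @ msg
            h = (own + agg).relu()
        else:
            h = own.relu()
    return h


def _dropout(
    t: Tensor, rate: float, training: bool, rng: Optional[np.random.Generator]
) -> Tensor:
    if not training or rate <= 0.0:
        return t
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    keep = (rng.random(t.data.shape) >= rate).astype(float) / (1.0 - rate)
    return t * keep


def cross_attention_block(
    params: dict[str, Tensor],
    block: int,
    h_p: Tensor,
    h_r: Tensor,
    n_heads: int,
    mask: Optional[np.ndarray] = None,
    dropout: float = 0.1,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """One reaction-attention block: product atoms attend to reactant atoms.

    ``mask`` is an additive (n_product x n_reactant) matrix (0 within a
    reaction, a large negative number across reactions) applied before the
    softmax.  The multi-head message is folded into the product features by
    a gated residual, layer norm, and a feed-forward sublayer.
    """
    d = h_p.data.shape[1]
    if h_r.data.shape[1] != d:
        raise ValueError("product/reactant feature dimensions differ")
    if d % n_heads:
        raise ValueError("hidden dimension must be divisible by the head count")
    dh = d // n_heads
    n_p, n_r = h_p.data.shape[0], h_r.data.shape[0]

    def _heads(x: Tensor, n: int) -> Tensor:
        return x.reshape(n, n_heads, dh).transpose(1, 0, 2)

    Q = _heads(h_p @ params[f"att{block}_Wq"], n_p)
    K = _heads(h_r @ params[f"att{block}_Wk"], n_r)
    V = _heads(h_r @ params[f"att{block}_Wv"], n_r)
    scores = (Q @ K.swap_last()) * (1.0 / math.sqrt(dh))
    if mask is not None:
        scores = scores + mask  # broadcast over heads
    attn = softmax(scores, axis=-1)
    attn = _dropout(attn, dropout, training, rng)
    message = (attn @ V).transpose(1, 0, 2).reshape(n_p, d)

    gate = (message @ params[f"att{block}_Wg"] + params[f"att{block}_bg"]).sigmoid()
    a = layer_norm(
        h_p + gate * message,
        params[f"att{block}_ln1_g"],
        params[f"att{block}_ln1_b"],
    )
    f = (a @ params[f"att{block}_Wf1"] + params[f"att{block}_bf1"]).relu()
    f = f @ params[f"att{block}_Wf2"] + params[f"att{block}_bf2"]
    return layer_norm(a + f, params[f"att{block}_ln2_g"], params[f"att{block}_ln2_b"])


def cross_attend(
    params: dict[str, Tensor],
    h_p: Tensor,
    h_r: Tensor,
    attention_blocks: int,
    n_heads: int,
    mask: Optional[np.ndarray] = None,
    dropout: float = 0.1,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    for b in range(attention_blocks):
        h_p = cross_attention_block(
            params, b, h_p, h_r, n_heads, mask, dropout, training, rng
        )
    return h_p


def classifier_scores(
    params: dict[str, Tensor],
    h_r: Tensor,
    h_p: Tensor,
    mask: Optional[np.ndarray] = None,
) -> Tensor:
    """Single-head attention classifier: row-softmax over reactant atoms of
    ``K_p Q_r^T / sqrt(d)`` gives ``P[u_p, u_r] = p(u_r | u_p)``."""
    if h_r.data.shape[0] == 0:
        raise ValueError("empty reactant atom set")
    d = h_p.data.shape[1]
    Qr = h_r @ params["clf_Wq"]
    Kp = h_p @ params["clf_Wk"]
    scores = (Kp @ Qr.swap_last()) * (1.0 / math.sqrt(d))
    if mask is not None:
        scores = scores + mask
    return softmax(scores, axis=-1)
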