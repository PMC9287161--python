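"""Desk-scale sequence encoder.

A windowed convolutional encoder: each position is represented by the
embeddings of the residues in a fixed window around it (out-of-range
positions use dedicated start/end marker embeddings) concatenated with
the organism-group embedding, followed by one tanh layer.  The output is
a T x D matrix aligned to the input residues, deterministic given
parameters and input.  The contract mirrors a large protein language
model closely enough that one could be wrapped behind the same
interface, but this encoder trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scales import AMINO_ACIDS
from .types import OrganismGroup

#: Residue token indices: 20 amino acids then UNK.
RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNK_INDEX = len(AMINO_ACIDS)
N_RESIDUE_TOKENS = UNK_INDEX + 1

GROUP_INDEX = {g: i for i, g in enumerate(OrganismGroup)}
N_GROUP_TOKENS = len(GROUP_INDEX)


def tokenize(sequence: str) -> np.ndarray:
    """Map a sequence to residue token indices; non-standard -> UNK."""
    if not sequence:
        raise ValueError("empty sequence")
    return np.array(
        [RESIDUE_INDEX.get(aa, UNK_INDEX) for aa in sequence.upper()],
        dtype=int,
    )


@dataclass
class EncoderParams:
    """Learnable parameters of the window encoder."""

    emb: np.ndarray       # (n_residue_tokens, E)
    group_emb: np.ndarray  # (n_group_tokens, E)
    bos: np.ndarray       # (E,) start-marker embedding
    eos: np.ndarray       # (E,) end-marker embedding
    W1: np.ndarray        # (window * E + E, D)
    b1: np.ndarray        # (D,)
    window_radius: int = 3
    emb_dim: int = field(default=8)
    hidden_dim: int = field(default=64)

    @classmethod
    def init(cls, rng: np.random.Generator, emb_dim: int = 8,
             hidden_dim: int = 64, window_radius: int = 3) -> "EncoderParams":
        window = 2 * window_radius + 1
        in_dim = window * emb_dim + emb_dim
        scale = 1.0 / np.sqrt(in_dim)
        return cls(
            emb=rng.normal(0.0, 0.5, size=(N_RESIDUE_TOKENS, emb_dim)),
            group_emb=rng.normal(0.0, 0.5, size=(N_GROUP_TOKENS, emb_dim)),
            bos=rng.normal(0.0, 0.5, size=emb_dim),
            eos=rng.normal(0.0, 0.5, size=emb_dim),
            W1=rng.normal(0.0, scale, size=(in_dim, hidden_dim)),
            b1=np.zeros(hidden_dim),
            window_radius=window_radius,
            emb_dim=emb_dim,
            hidden_dim=hidden_dim,
        )


def _window_tokens(tokens: np.ndarray, radius: int) -> np.ndarray:
    """(T, window) token indices with -1 (BOS side) / -2 (EOS side)."""
    t_len = tokens.shape[0]
    cols = []
    for off in range(-radius, radius + 1):
        idx = np.arange(t_len) + off
        col = np.where(idx < 0, -1, np.where(idx >= t_len, -2, tokens[np.clip(idx, 0, t_len - 1)]))
        cols.append(col)
    return np.stack(cols, axis=1)


def encode(sequence: str, group: OrganismGroup,
           params: EncoderParams) -> np.ndarray:
    """T x D hidden states for a sequence (inference path, no dropout)."""
    h, _ = encode_forward(tokenize(sequence), GROUP_INDEX[group], params)
    return h


def encode_forward(tokens: np.ndarray, group_idx: int,
                   params: EncoderParams):
    """Forward pass returning hidden states and a backprop cache."""
    radius = params.window_radius
    win = _window_tokens(tokens, radius)          # (T, W)
    t_len, w = win.shape
    e_dim = params.emb_dim

    feats = np.empty((t_len, w * e_dim + e_dim))
    for k in range(w):
        col = win[:, k]
        block = np.where(
            (col == -1)[:, None], params.bos[None, :],
            np.where((col == -2)[:, None], params.eos[None, :],
                     params.emb[np.clip(col, 0, None)]),
        )
        feats[:, k * e_dim:(k + 1) * e_dim] = block
    feats[:, w * e_dim:] = params.group_emb[group_idx]

    pre = feats @ params.W1 + params.b1
    h = np.tanh(pre)
    cache = (win, feats, h, group_idx)
    return h, cache


def encode_backward(d_h: np.ndarray, cache, params: EncoderParams) -> dict:
    """Gradients of a scalar loss w.r.t. all encoder parameters."""
    win, feats, h, group_idx = cache
    t_len, w = win.shape
    e_dim = params.emb_dim

    d_pre = d_h * (1.0 - h * h)
    grads = {
        "W1": feats.T @ d_pre,
        "b1": d_pre.sum(axis=0),
        "emb": np.zeros_like(params.emb),
        "group_emb": np.zeros_like(params.group_emb),
        "bos": np.zeros_like(params.bos),
        "eos": np.zeros_like(params.eos),
    }
    d_feats = d_pre @ params.W1.T
    for k in range(w):
        block = d_feats[:, k * e_dim:(k + 1) * e_dim]
        col = win[:, k]
        is_bos, is_eos = col == -1, col == -2
        if is_bos.any():
            grads["bos"] += block[is_bos].sum(axis=0)
        if is_eos.any():
            grads["eos"] += block[is_eos].sum(axis=0)
        real = ~(is_bos | is_eos)
        np.add.at(grads["emb"], col[real], block[real])
    grads["group_emb"][group_idx] = d_feats[:, w * e_dim:].sum(axis=0)
    return grads
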