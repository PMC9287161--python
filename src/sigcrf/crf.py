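"""Grammar-constrained linear-chain CRF.

All lattice computations run in log space.  Disallowed transitions and
start/end states carry a large negative constant rather than -inf so that
masked arithmetic stays NaN-free; anything below ``-1e20`` is treated as
"no path".

Besides the standard forward/backward/Viterbi trio this module provides
the multitag negative log likelihood (a forward pass on the lattice
restricted to the per-position admissible-state sets) and a hand-derived
vector-Jacobian product through the forward-backward recursions, needed
to differentiate losses defined on the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grammar import StateSpace
from .types import SpClass

NEG = -1.0e30
_NO_PATH = -1.0e20


class NoPathError(ValueError):
    """No state path is consistent with the mask (and tag restriction)."""


@dataclass
class CrfParams:
    """Emission projection and transition scores.

    ``phi`` holds learnable scores at allowed transitions and ``NEG`` at
    masked entries; :meth:`masked_phi` re-applies the mask defensively.
    """

    W_psi: np.ndarray  # (D, C)
    b_psi: np.ndarray  # (C,)
    phi: np.ndarray    # (C, C)

    def masked_phi(self, space: StateSpace) -> np.ndarray:
        return np.where(space.allowed, self.phi, NEG)

    @classmethod
    def init(cls, hidden_dim: int, space: StateSpace, rng: np.random.Generator,
             scale: float = 0.1) -> "CrfParams":
        c = space.n_states
        w = rng.normal(0.0, scale, size=(hidden_dim, c))
        b = np.zeros(c)
        phi = np.where(space.allowed, rng.normal(0.0, scale, size=(c, c)), NEG)
        return cls(W_psi=w, b_psi=b, phi=phi)


@dataclass
class Prediction:
    """Full per-sequence output of the predictor."""

    path: np.ndarray           # (T,) state ids
    marginals: np.ndarray      # (T, C) row-stochastic
    class_probs: np.ndarray    # (6,) ordered as list(SpClass)
    predicted_class: SpClass
    cs: Optional[int]          # 1-based, None if no SP decoded
    cs_prob: float


def emissions(hidden: np.ndarray, params: CrfParams) -> np.ndarray:
    """ψ(h_t) = W_ψ h_t + b_ψ, rows aligned to sequence positions."""
    hidden = np.asarray(hidden, dtype=float)
    if hidden.ndim != 2 or hidden.shape[1] != params.W_psi.shape[0]:
        raise ValueError(
            f"hidden shape {hidden.shape} incompatible with W_psi "
            f"{params.W_psi.shape}"
        )
    return hidden @ params.W_psi + params.b_psi


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.sum(np.exp(x - m), axis=axis))
    return out


def _restrict(em: np.ndarray, tag_sets) -> np.ndarray:
    """Mask emissions outside the admissible set at each position."""
    e = np.full_like(em, NEG)
    for t, allowed in enumerate(tag_sets):
        idx = sorted(allowed)
        e[t, idx] = em[t, idx]
    return e


def _forward(em: np.ndarray, phi: np.ndarray, space: StateSpace,
             check_feasible: bool = False) -> np.ndarray:
    """Log-alpha lattice; optionally raise at the first dead position."""
    t_len, _ = em.shape
    la = np.empty_like(em)
    la[0] = em[0] + np.where(space.start_allowed, 0.0, NEG)
    if check_feasible and la[0].max() < _NO_PATH:
        raise NoPathError("no admissible state at position 1")
    for t in range(1, t_len):
        la[t] = em[t] + _lse(la[t - 1][:, None] + phi, axis=0)
        if check_feasible and la[t].max() < _NO_PATH:
            raise NoPathError(f"no admissible path through position {t + 1}")
    return la


def _backward(em: np.ndarray, phi: np.ndarray, space: StateSpace) -> np.ndarray:
    t_len, _ = em.shape
    lb = np.empty_like(em)
    lb[-1] = np.where(space.end_allowed, 0.0, NEG)
    for t in range(t_len - 2, -1, -1):
        lb[t] = _lse(phi + (em[t + 1] + lb[t + 1])[None, :], axis=1)
    return lb


def log_partition(em: np.ndarray, params: CrfParams, space: StateSpace,
                  tag_sets=None) -> float:
    """log Z over allowed paths (optionally restricted to tag sets)."""
    if em.shape[0] < 1:
        raise ValueError("empty sequence")
    if tag_sets is not None:
        em = _restrict(em, tag_sets)
    phi = params.masked_phi(space)
    la = _forward(em, phi, space, check_feasible=tag_sets is not None)
    log_z = float(_lse(la[-1] + np.where(space.end_allowed, 0.0, NEG), axis=0))
    if log_z < _NO_PATH:
        raise NoPathError("no allowed path through the lattice")
    return log_z


def marginals(em: np.ndarray, params: CrfParams, space: StateSpace,
              with_lattices: bool = False):
    """Posterior state probabilities per position (forward-backward)."""
    phi = params.masked_phi(space)
    la = _forward(em, phi, space)
    lb = _backward(em, phi, space)
    log_z = float(_lse(la[-1] + np.where(space.end_allowed, 0.0, NEG), axis=0))
    if log_z < _NO_PATH:
        raise NoPathError("no allowed path through the lattice")
    with np.errstate(under="ignore"):
        p = np.exp(la + lb - log_z)  # masked entries underflow to exact 0
    p /= p.sum(axis=1, keepdims=True)
    if with_lattices:
        return p, la, lb, log_z
    return p


def edge_marginals(em: np.ndarray, params: CrfParams,
                   space: StateSpace) -> np.ndarray:
    """Expected transition counts E[#(i -> j)], a (C, C) matrix."""
    phi = params.masked_phi(space)
    la = _forward(em, phi, space)
    lb = _backward(em, phi, space)
    log_z = float(_lse(la[-1] + np.where(space.end_allowed, 0.0, NEG), axis=0))
    if log_z < _NO_PATH:
        raise NoPathError("no allowed path through the lattice")
    counts = np.zeros_like(phi)
    for t in range(em.shape[0] - 1):
        lp = (la[t][:, None] + phi + (em[t + 1] + lb[t + 1])[None, :]) - log_z
        with np.errstate(under="ignore"):
            counts += np.exp(lp)
    return counts


def viterbi(em: np.ndarray, params: CrfParams, space: StateSpace,
            tag_sets=None) -> np.ndarray:
    """Highest-scoring allowed path; ties resolved deterministically by
    preferring the lowest state id during the backward trace."""
    if em.shape[0] < 1:
        raise ValueError("empty sequence")
    if tag_sets is not None:
        em = _restrict(em, tag_sets)
    phi = params.masked_phi(space)
    t_len, c = em.shape
    score = em[0] + np.where(space.start_allowed, 0.0, NEG)
    back = np.zeros((t_len, c), dtype=int)
    for t in range(1, t_len):
        cand = score[:, None] + phi
        back[t] = np.argmax(cand, axis=0)
        score = em[t] + cand[back[t], np.arange(c)]
    final = score + np.where(space.end_allowed, 0.0, NEG)
    if final.max() < _NO_PATH:
        raise NoPathError("no allowed path through the lattice")
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(final))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_score(path: Sequence[int], em: np.ndarray, params: CrfParams,
               space: StateSpace) -> float:
    """Unnormalized log score of one path (NEG-masked if illegal)."""
    phi = params.masked_phi(space)
    s = float(em[0, path[0]])
    s += 0.0 if space.start_allowed[path[0]] else NEG
    for t in range(1, len(path)):
        s += float(phi[path[t - 1], path[t]]) + float(em[t, path[t]])
    s += 0.0 if space.end_allowed[path[-1]] else NEG
    return s


def multitag_nll(em: np.ndarray, params: CrfParams, space: StateSpace,
                 tags) -> float:
    """log Z - log Z_constrained, marginalizing over all paths that stay
    inside the admissible set at every position."""
    sets = tags.sets if hasattr(tags, "sets") else tags
    if len(sets) != em.shape[0]:
        raise ValueError("tag matrix length does not match sequence length")
    log_z = log_partition(em, params, space)
    log_z_c = log_partition(em, params, space, tag_sets=sets)
    return log_z - log_z_c


def class_probs(marg: np.ndarray, space: StateSpace) -> np.ndarray:
    """Mean-over-positions marginal mass per global class (6-vector)."""
    t_len = marg.shape[0]
    out = np.zeros(len(SpClass))
    cls_idx = space.class_of_state
    for gi in range(len(SpClass)):
        out[gi] = marg[:, cls_idx == gi].sum() / t_len
    return out


def infer_cs(path: Sequence[int], space: StateSpace) -> Optional[int]:
    """1-based position of the last SP state on the path, or None."""
    sp_mask = space.sp_state_mask
    cs = None
    for t, state in enumerate(path):
        if sp_mask[state]:
            cs = t + 1
    return cs


def decode(em: np.ndarray, params: CrfParams, space: StateSpace) -> Prediction:
    """Marginals + Viterbi + class probabilities + CS for one emission
    matrix (the encoder-independent part of prediction)."""
    marg = marginals(em, params, space)
    path = viterbi(em, params, space)
    probs = class_probs(marg, space)
    order = list(SpClass)
    predicted = order[int(np.argmax(probs))]
    cs = infer_cs(path, space)
    cs_prob = float(marg[cs - 1, path[cs - 1]]) if cs is not None else 0.0
    return Prediction(
        path=path, marginals=marg, class_probs=probs,
        predicted_class=predicted, cs=cs, cs_prob=cs_prob,
    )


def marginals_vjp(em: np.ndarray, params: CrfParams, space: StateSpace,
                  grad_marg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Backpropagate dL/d(marginals) to (dL/d(emissions), dL/d(phi)).

    Reverse-mode differentiation of the forward-backward recursions:

        la[0]  = e[0] + start_mask
        la[t]  = e[t] + LSE_j(la[t-1, j] + phi[j, :])
        lb[T-1] = end_mask
        lb[t]  = LSE_k(phi[:, k] + e[t+1, k] + lb[t+1, k])
        logZ   = LSE_c(la[T-1, c] + end_mask[c])
        p[t]   = exp(la[t] + lb[t] - logZ)

    The adjoints of the LSE steps are softmax-weighted sums; columns that
    are fully masked receive zero adjoint because p (and hence the seed
    gradient) vanishes there.
    """
    phi = params.masked_phi(space)
    p, la, lb, log_z = marginals(em, params, space, with_lattices=True)
    t_len, c = em.shape

    seed = grad_marg * p                     # dL/d(la) and dL/d(lb) direct
    d_log_z = -float(seed.sum())

    d_em = np.zeros_like(em)
    d_phi = np.zeros_like(phi)

    # ---- alpha chain (descending t) ----
    end_scores = la[-1] + np.where(space.end_allowed, 0.0, NEG)
    w_end = _softmax_safe(end_scores)
    adj = seed[-1] + d_log_z * w_end
    for t in range(t_len - 1, 0, -1):
        # la[t] = e[t] + LSE_j(la[t-1] + phi[:, c])
        d_em[t] += adj
        scores = la[t - 1][:, None] + phi    # (j, c)
        w = _softmax_cols(scores)            # normalized over j per column c
        d_phi += w * adj[None, :]
        prev = w @ adj                       # (j,)
        adj = seed[t - 1] + prev
    d_em[0] += adj

    # ---- beta chain (ascending t) ----
    adj_b = seed[0]
    for t in range(0, t_len - 1):
        # lb[t, j] = LSE_k(phi[j, :] + e[t+1] + lb[t+1])
        scores = phi + (em[t + 1] + lb[t + 1])[None, :]  # (j, k)
        u = _softmax_rows(scores)            # normalized over k per row j
        contrib = u * adj_b[:, None]         # (j, k)
        d_phi += contrib
        col = contrib.sum(axis=0)            # (k,)
        d_em[t + 1] += col
        adj_b = seed[t + 1] + col

    d_phi[~space.allowed] = 0.0
    return d_em, d_phi


def _softmax_safe(x: np.ndarray) -> np.ndarray:
    m = x.max()
    e = np.exp(x - m)
    return e / e.sum()


def _softmax_cols(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=0, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=0, keepdims=True)


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=1, keepdims=True)
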