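"""Composition-divergence regularizer and the degenerate-run detector.

Soft per-region amino acid score vectors are accumulated from the CRF
marginals (states pooled across classes by region kind), normalized, and
penalized by the cosine similarity between adjacent regions (n vs h and
h vs c).  Because scores are nonnegative, each cosine lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .crf import Prediction
from .encoder import RESIDUE_INDEX
from .grammar import StateSpace
from .scales import AMINO_ACIDS
from .types import SpClass

REGIONS = ("n", "h", "c")

#: Degeneracy threshold: flag runs whose mean predicted n-region length
#: collapses to (nearly) the minimum of 2.
DEGENERACY_TOLERANCE = 0.05


@dataclass
class RegionScoreVector:
    """Soft amino acid composition score of one region of one sequence."""

    region: str
    scores: np.ndarray  # (20,) nonnegative, indexed like AMINO_ACIDS

    @property
    def total(self) -> float:
        return float(self.scores.sum())

    def normalized(self) -> Optional[np.ndarray]:
        s = self.total
        if s <= 0.0:
            return None
        return self.scores / s


def region_state_masks(space: StateSpace) -> dict[str, np.ndarray]:
    """Boolean state masks for the n/h/c region kinds, pooled over classes."""
    return {r: space.region_kind_mask(r) for r in REGIONS}


def region_scores(marg: np.ndarray, sequence: str,
                  space: StateSpace) -> dict[str, RegionScoreVector]:
    """score_{a,r} = sum_t 1[x_t = a] * sum_{c in r} marginal[t, c]."""
    masks = region_state_masks(space)
    n_aa = len(AMINO_ACIDS)
    out = {}
    aa_idx = np.array([RESIDUE_INDEX.get(ch, -1) for ch in sequence.upper()])
    for r, mask in masks.items():
        s_t = marg[:, mask].sum(axis=1)           # (T,)
        scores = np.zeros(n_aa)
        valid = aa_idx >= 0                       # UNK residues excluded
        np.add.at(scores, aa_idx[valid], s_t[valid])
        out[r] = RegionScoreVector(region=r, scores=scores)
    return out


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(a @ b / (na * nb))


def similarity_terms(vectors: dict[str, RegionScoreVector],
                     eps: float = 1e-12) -> dict[str, Optional[float]]:
    """cos(n', h') and cos(h', c') for one sequence; None where a region
    is absent (zero total score) and the term must be skipped."""
    out: dict[str, Optional[float]] = {}
    for key, (r1, r2) in {"nh": ("n", "h"), "hc": ("h", "c")}.items():
        v1, v2 = vectors[r1].normalized(), vectors[r2].normalized()
        if v1 is None or v2 is None:
            out[key] = None
        else:
            out[key] = cosine(v1, v2)
    return out


def reg_loss(batch_vectors: Iterable[dict[str, RegionScoreVector]],
             alpha: float) -> float:
    """alpha * (mean cos(n,h) + mean cos(h,c)) over the batch, each mean
    taken over the sequences where the term is defined."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    nh, hc = [], []
    for vectors in batch_vectors:
        terms = similarity_terms(vectors)
        if terms["nh"] is not None:
            nh.append(terms["nh"])
        if terms["hc"] is not None:
            hc.append(terms["hc"])
    loss = 0.0
    if nh:
        loss += float(np.mean(nh))
    if hc:
        loss += float(np.mean(hc))
    return alpha * loss


def _cosine_grad(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """cos(a, b) and its gradients w.r.t. the raw (unnormalized) vectors.

    The sum-normalization used for the score vectors is a positive
    scaling, under which the cosine is invariant, so differentiating the
    cosine of the raw vectors gives the same loss surface.
    """
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    c = float(a @ b / (na * nb))
    da = b / (na * nb) - c * a / (na * na)
    db = a / (na * nb) - c * b / (nb * nb)
    return c, da, db


def reg_terms_and_grads(vectors: dict[str, RegionScoreVector]):
    """Per-sequence similarity terms with gradients w.r.t. score vectors.

    Returns ``{"nh": (value, {region: grad})...}`` with ``None`` for
    skipped terms (absent / zero-norm region).
    """
    out = {}
    for key, (r1, r2) in {"nh": ("n", "h"), "hc": ("h", "c")}.items():
        a, b = vectors[r1].scores, vectors[r2].scores
        if a.sum() <= 0.0 or b.sum() <= 0.0:
            out[key] = None
            continue
        c, da, db = _cosine_grad(a, b)
        out[key] = (c, {r1: da, r2: db})
    return out


def scores_grad_to_marginals(d_scores: dict[str, np.ndarray], sequence: str,
                             marg_shape: tuple[int, int],
                             space: StateSpace) -> np.ndarray:
    """Chain d(loss)/d(score vectors) back to d(loss)/d(marginals)."""
    masks = region_state_masks(space)
    d_marg = np.zeros(marg_shape)
    aa_idx = np.array([RESIDUE_INDEX.get(ch, -1) for ch in sequence.upper()])
    valid = aa_idx >= 0
    for r, d_vec in d_scores.items():
        per_pos = np.zeros(marg_shape[0])
        per_pos[valid] = d_vec[aa_idx[valid]]
        d_marg += per_pos[:, None] * masks[r][None, :]
    return d_marg


def predicted_n_length(prediction: Prediction, space: StateSpace) -> Optional[int]:
    """Number of n-kind states on the decoded path, or None if the
    predicted class has no n-region (NO_SP, SPIII)."""
    if prediction.predicted_class in (SpClass.NO_SP, SpClass.SEC_SPIII):
        return None
    n_mask = space.region_kind_mask("n")
    return int(n_mask[prediction.path].sum())


def detect_degenerate(epoch_predictions: Iterable[Prediction],
                      space: StateSpace,
                      tolerance: float = DEGENERACY_TOLERANCE) -> bool:
    """True iff the mean predicted n-region length has collapsed to the
    minimum (<= 2 + tolerance).  Indeterminate (no SP predictions with an
    n-region) returns False with a warning."""
    lengths = [
        n for p in epoch_predictions
        if (n := predicted_n_length(p, space)) is not None
    ]
    if not lengths:
        warnings.warn(
            "degeneracy check indeterminate: no SP predictions with an "
            "n-region in the validation slice",
            stacklevel=2,
        )
        return False
    return float(np.mean(lengths)) <= 2.0 + tolerance
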