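"""Independent oracles used across the test suite.

Everything here is deliberately written without reference to the package
internals it checks: exhaustive path enumeration for lattice quantities,
a quadratic-DP Gotoh aligner for identities, direct summations for
aggregate statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1.0e30


@dataclass
class TinySpace:
    """Minimal stand-in for a state space in oracle tests."""

    allowed: np.ndarray
    start_allowed: np.ndarray
    end_allowed: np.ndarray

    @property
    def n_states(self) -> int:
        return self.allowed.shape[0]


def random_tiny_space(rng: np.random.Generator, n_states: int,
                      density: float = 0.6) -> TinySpace:
    while True:
        allowed = rng.random((n_states, n_states)) < density
        start = rng.random(n_states) < 0.7
        end = rng.random(n_states) < 0.7
        if start.any() and end.any():
            return TinySpace(allowed, start, end)


def enumerate_paths(space, t_len: int):
    """All start/end/transition-legal paths of length t_len."""
    c = space.n_states
    for p in itertools.product(range(c), repeat=t_len):
        if not space.start_allowed[p[0]] or not space.end_allowed[p[-1]]:
            continue
        if all(space.allowed[p[i], p[i + 1]] for i in range(t_len - 1)):
            yield p


def path_log_score(path, em: np.ndarray, phi: np.ndarray) -> float:
    s = em[0, path[0]]
    for i in range(1, len(path)):
        s += phi[path[i - 1], path[i]] + em[i, path[i]]
    return float(s)


def brute_force_lattice(space, em: np.ndarray, phi: np.ndarray):
    """(log Z, marginals, best path score) by exhaustive enumeration."""
    paths = list(enumerate_paths(space, em.shape[0]))
    if not paths:
        return None
    scores = np.array([path_log_score(p, em, phi) for p in paths])
    log_z = float(np.logaddexp.reduce(scores))
    weights = np.exp(scores - log_z)
    marg = np.zeros_like(em)
    for p, w in zip(paths, weights):
        for t, s in enumerate(p):
            marg[t, s] += w
    return log_z, marg, float(scores.max()), paths, scores


_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_align(a: str, b: str, gap_open: float = -11.0,
                gap_extend: float = -1.0):
    """Affine-gap global alignment oracle: (score, identity)."""
    n, m = len(a), len(b)
    big_neg = -1e9
    mm = np.full((n + 1, m + 1), big_neg)
    gx = np.full((n + 1, m + 1), big_neg)  # gap in b (vertical)
    gy = np.full((n + 1, m + 1), big_neg)  # gap in a (horizontal)
    mm[0, 0] = 0.0
    for i in range(1, n + 1):
        gx[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        gy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            mm[i, j] = max(mm[i - 1, j - 1], gx[i - 1, j - 1],
                           gy[i - 1, j - 1]) + s
            gx[i, j] = max(mm[i - 1, j] + gap_open, gx[i - 1, j] + gap_extend,
                           gy[i - 1, j] + gap_open)
            gy[i, j] = max(mm[i, j - 1] + gap_open, gy[i, j - 1] + gap_extend,
                           gx[i, j - 1] + gap_open)
    score = max(mm[n, m], gx[n, m], gy[n, m])

    i, j = n, m
    state = int(np.argmax([mm[n, m], gx[n, m], gy[n, m]]))
    identical = aligned = 0
    while i > 0 or j > 0:
        aligned += 1
        if state == 0:
            identical += a[i - 1] == b[j - 1]
            state = int(np.argmax([mm[i - 1, j - 1], gx[i - 1, j - 1],
                                   gy[i - 1, j - 1]]))
            i, j = i - 1, j - 1
        elif state == 1:
            cands = [mm[i - 1, j] + gap_open, gx[i - 1, j] + gap_extend,
                     gy[i - 1, j] + gap_open]
            state = int(np.argmax(cands))
            i -= 1
        else:
            cands = [mm[i, j - 1] + gap_open, gy[i, j - 1] + gap_extend,
                     gx[i, j - 1] + gap_open]
            state = [0, 2, 1][int(np.argmax(cands))]
            j -= 1
    return float(score), identical / aligned


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
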