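"""Homology-aware dataset partitioning.

Pairwise global identities (Needleman-Wunsch, BLOSUM62, gap open -11 /
extend -1; identity = identical columns / alignment length including
gaps) feed single-linkage clustering at the identity threshold; clusters
are greedily packed into the requested number of partitions per class,
balancing size and organism-group composition; finally, sequences with
cross-partition identities above the threshold are removed greedily
(most violations first) until the threshold holds exhaustively.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .types import OrganismGroup, SequenceRecord, SpClass

REMOVED = -1


def make_aligner(gap_open: float = -11.0, gap_extend: float = -1.0,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER: Optional[Align.PairwiseAligner] = None


def _default_aligner() -> Align.PairwiseAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = make_aligner()
    return _DEFAULT_ALIGNER


def pairwise_identity(a: str, b: str,
                      aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Global-alignment identity in [0, 1] (gap columns count in the
    denominator)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = aligner or _default_aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def identity_matrix(records: Sequence[SequenceRecord],
                    aligner: Optional[Align.PairwiseAligner] = None,
                    ) -> np.ndarray:
    n = len(records)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(
                records[i].sequence, records[j].sequence, aligner)
    return mat


def single_linkage(identity: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the graph with edges identity > threshold."""
    n = identity.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [clusters[k] for k in sorted(clusters)]


@dataclass
class PartitionResult:
    assignment: dict[str, int]  # id -> partition index or REMOVED
    n_partitions: int
    removed: list[str] = field(default_factory=list)
    class_counts: list[Counter] = field(default_factory=list)
    group_counts: list[Counter] = field(default_factory=list)

    def partition_ids(self, k: int) -> list[str]:
        return [rid for rid, p in self.assignment.items() if p == k]


def _assign_clusters(clusters: list[list[int]],
                     records: Sequence[SequenceRecord],
                     n_partitions: int,
                     balance_weight: float = 2.0) -> list[int]:
    """Greedy cluster -> partition assignment minimizing a combined
    size + organism-group-imbalance objective."""
    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c]), clusters[c][0]))
    sizes = [0] * n_partitions
    group_tallies = [Counter() for _ in range(n_partitions)]
    result = [0] * len(clusters)
    for c in order:
        members = clusters[c]
        groups = Counter(records[i].organism_group for i in members)
        best, best_cost = 0, None
        for p in range(n_partitions):
            size_cost = sizes[p] + len(members)
            imbalance = 0.0
            for g, cnt in groups.items():
                tallies = [group_tallies[q][g] + (cnt if q == p else 0)
                           for q in range(n_partitions)]
                imbalance += max(tallies) - min(tallies)
            cost = size_cost + balance_weight * imbalance
            if best_cost is None or cost < best_cost:
                best, best_cost = p, cost
        result[c] = best
        sizes[best] += len(members)
        group_tallies[best].update(groups)
    return result


def _remove_violators(records: Sequence[SequenceRecord],
                      assignment: dict[str, int],
                      identity: dict[tuple[str, str], float],
                      threshold: float) -> list[str]:
    """Iteratively drop the sequence with the most cross-partition
    violations (ties broken by smaller id) until none remain."""
    removed: list[str] = []
    ids = [r.id for r in records]
    while True:
        violations = Counter()
        for i, a in enumerate(ids):
            if assignment[a] in (REMOVED,):
                continue
            for b in ids[i + 1:]:
                if assignment[b] in (REMOVED,):
                    continue
                if assignment[a] != assignment[b] and \
                        identity[(a, b)] > threshold:
                    violations[a] += 1
                    violations[b] += 1
        if not violations:
            return removed
        top = max(violations.values())  # ties broken by smaller id
        worst_id = min(k for k, v in violations.items() if v == top)
        assignment[worst_id] = REMOVED
        removed.append(worst_id)


def partition_dataset(records: Sequence[SequenceRecord],
                      threshold: float = 0.30,
                      n_partitions: int = 3,
                      aligner: Optional[Align.PairwiseAligner] = None,
                      ) -> PartitionResult:
    """Per-class clustering and partition packing, concatenated across
    classes, followed by global cross-partition violation removal."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    aligner = aligner or _default_aligner()
    assignment: dict[str, int] = {}
    pair_identity: dict[tuple[str, str], float] = {}

    for sp_class in SpClass:
        class_records = [r for r in records if r.sp_class is sp_class]
        if not class_records:
            continue
        mat = identity_matrix(class_records, aligner)
        for i, a in enumerate(class_records):
            for j in range(i + 1, len(class_records)):
                b = class_records[j]
                key = (min(a.id, b.id), max(a.id, b.id))
                pair_identity[key] = mat[i, j]
        clusters = single_linkage(mat, threshold)
        if len(clusters) < n_partitions:
            import warnings
            warnings.warn(
                f"{sp_class.value}: only {len(clusters)} clusters for "
                f"{n_partitions} partitions; some slots stay empty",
                stacklevel=2)
        cluster_parts = _assign_clusters(clusters, class_records, n_partitions)
        for c, members in enumerate(clusters):
            for i in members:
                assignment[class_records[i].id] = cluster_parts[c]

    # identities across classes (needed for the global violation scan)
    ordered = sorted(records, key=lambda r: r.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            key = (a.id, b.id)
            if key not in pair_identity:
                pair_identity[key] = pairwise_identity(
                    a.sequence, b.sequence, aligner)

    lookup = {(a, b): pair_identity[(min(a, b), max(a, b))]
              for i, a in enumerate(sorted(assignment))
              for b in sorted(assignment)[i + 1:]}
    removed = _remove_violators(ordered, assignment, lookup, threshold)

    class_counts = [Counter() for _ in range(n_partitions)]
    group_counts = [Counter() for _ in range(n_partitions)]
    by_id = {r.id: r for r in records}
    for rid, p in assignment.items():
        if p == REMOVED:
            continue
        class_counts[p][by_id[rid].sp_class] += 1
        group_counts[p][by_id[rid].organism_group] += 1
    return PartitionResult(
        assignment=assignment, n_partitions=n_partitions, removed=removed,
        class_counts=class_counts, group_counts=group_counts)


def max_identity_to_set(sequence: str,
                        training: Sequence[SequenceRecord],
                        aligner: Optional[Align.PairwiseAligner] = None,
                        ) -> float:
    if not training:
        raise ValueError("empty training set")
    return max(pairwise_identity(sequence, t.sequence, aligner)
               for t in training)


def bin_by_max_identity(removed: Sequence[SequenceRecord],
                        training: Sequence[SequenceRecord],
                        bin_edges: Sequence[float],
                        aligner: Optional[Align.PairwiseAligner] = None,
                        ) -> dict[str, tuple[int, float]]:
    """Map each removed-set sequence id to (bin index, max identity).

    Bins are half-open ``[edge_k, edge_{k+1})`` with the last bin closed
    on the right.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing, >= 2 values")
    out = {}
    for rec in removed:
        ident = max_identity_to_set(rec.sequence, training, aligner)
        k = None
        for b in range(len(edges) - 1):
            last = b == len(edges) - 2
            if edges[b] <= ident < edges[b + 1] or (last and ident == edges[-1]):
                k = b
                break
        out[rec.id] = (k, ident) if k is not None else (None, ident)
    return out
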