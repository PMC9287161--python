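"""Evaluation metrics: detection MCC (two negative-set modes), CS
precision/recall with tolerance windows, Gorodkin multiclass MCC, and
identity-stratified performance."""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import OrganismGroup, SpClass


class MccMode(enum.Enum):
    #: negatives = soluble/transmembrane only; other SP types excluded
    MCC1 = 1
    #: negatives additionally include all other SP types
    MCC2 = 2


@dataclass
class EvalRecord:
    id: str
    true_class: SpClass
    predicted_class: SpClass
    true_cs: Optional[int] = None
    predicted_cs: Optional[int] = None
    organism_group: OrganismGroup = OrganismGroup.UNKNOWN
    max_train_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.true_class.is_sp and self.true_cs is None:
            raise ValueError(f"{self.id}: SP record requires a true CS")
        if not self.true_class.is_sp and self.true_cs is not None:
            raise ValueError(f"{self.id}: NO_SP record cannot carry a CS")


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Binary MCC; degenerate margins give 0 with a warning."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        warnings.warn("degenerate confusion matrix: MCC set to 0",
                      stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / denom


def detection_mcc(records: Sequence[EvalRecord], sp_type: SpClass,
                  group: Optional[OrganismGroup] = None,
                  mode: MccMode = MccMode.MCC2) -> float:
    """Binary detection MCC under the chosen negative set.

    ``sp_type`` may be NO_SP under MCC2 (positives = negatives-of-SP),
    where the MCC1/MCC2 distinction collapses; MCC1 requires an SP type.
    """
    if not sp_type.is_sp and mode is MccMode.MCC1:
        raise ValueError("MCC1 is undefined for NO_SP as the positive class")
    subset = [r for r in records
              if group is None or r.organism_group is group]
    if mode is MccMode.MCC1:
        subset = [r for r in subset
                  if r.true_class is sp_type
                  or r.true_class is SpClass.NO_SP]
    tp = tn = fp = fn = 0
    for r in subset:
        truth = r.true_class is sp_type
        pred = r.predicted_class is sp_type
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return mcc_from_counts(tp, tn, fp, fn)


def cs_precision_recall(records: Sequence[EvalRecord], sp_type: SpClass,
                        window: int = 0) -> tuple[float, float]:
    """CS precision/recall for one SP type at a tolerance window.

    A prediction is correct iff the predicted class matches the true
    class and |predicted CS - true CS| <= window; a CS predicted under
    the wrong class counts as "no CS predicted".
    """
    if window not in (0, 1, 2, 3):
        raise ValueError("window must be in {0, 1, 2, 3}")
    n_predicted = sum(
        1 for r in records
        if r.predicted_class is sp_type and r.predicted_cs is not None)
    n_true = sum(1 for r in records if r.true_class is sp_type)
    correct = sum(
        1 for r in records
        if r.true_class is sp_type and r.predicted_class is sp_type
        and r.predicted_cs is not None and r.true_cs is not None
        and abs(r.predicted_cs - r.true_cs) <= window)
    if n_predicted == 0:
        warnings.warn(f"no predicted CSs for {sp_type.value}: precision "
                      "reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = correct / n_predicted
    recall = correct / n_true if n_true else 0.0
    return precision, recall


def confusion_matrix(records: Sequence[EvalRecord]) -> np.ndarray:
    order = list(SpClass)
    idx = {c: i for i, c in enumerate(order)}
    mat = np.zeros((len(order), len(order)), dtype=float)
    for r in records:
        mat[idx[r.true_class], idx[r.predicted_class]] += 1
    return mat


def gorodkin_mcc(confusion: np.ndarray) -> float:
    """K-category correlation coefficient from a K x K confusion matrix
    (rows = truth, columns = prediction)."""
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    trace = np.trace(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    cov_xy = trace * n - row @ col
    cov_xx = n * n - row @ row
    cov_yy = n * n - col @ col
    denom = math.sqrt(cov_xx) * math.sqrt(cov_yy)
    if denom == 0.0:
        warnings.warn("degenerate confusion matrix: multiclass MCC set to 0",
                      stacklevel=2)
        return 0.0
    return cov_xy / denom


def multiclass_mcc(records: Sequence[EvalRecord]) -> float:
    classes = {r.true_class for r in records} | \
              {r.predicted_class for r in records}
    if len(classes) < 2:
        raise ValueError("multiclass MCC requires >= 2 classes present")
    return gorodkin_mcc(confusion_matrix(records))


DEFAULT_IDENTITY_BINS = tuple(np.round(np.arange(0.3, 1.01, 0.1), 10))


def performance_by_identity_bin(
    records: Sequence[EvalRecord],
    bin_edges: Sequence[float] = DEFAULT_IDENTITY_BINS,
) -> dict[int, float]:
    """Multiclass MCC per max-train-identity bin; empty bins absent."""
    edges = list(bin_edges)
    binned: dict[int, list[EvalRecord]] = {}
    for r in records:
        if r.max_train_identity is None:
            raise ValueError(f"{r.id}: missing max train identity")
        for b in range(len(edges) - 1):
            last = b == len(edges) - 2
            if edges[b] <= r.max_train_identity < edges[b + 1] or \
                    (last and r.max_train_identity == edges[-1]):
                binned.setdefault(b, []).append(r)
                break
    return {b: gorodkin_mcc(confusion_matrix(rs))
            for b, rs in sorted(binned.items())}
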