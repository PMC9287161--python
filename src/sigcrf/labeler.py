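"""Rule-based multitag region labels for annotated signal peptides.

The rules produce weak-supervision targets: most positions carry a single
admissible state, positions between the fixed anchor points carry the
two-element ambiguity sets {n, h} or {h, c} of one class.  Minimum region
lengths are two residues for the initial n-region and three for the
terminal c-region; the h-region anchor is the most hydrophobic position
found with a 7-residue Kyte-Doolittle window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .grammar import StateSpace
from .scales import kd_value
from .types import OrganismGroup, SequenceRecord, SpClass

N_MIN = 2           # minimum n-region length
C_MIN = 3           # minimum c-region length (also the lipobox length)
KD_WINDOW = 7


class LabelingError(ValueError):
    """Raised when the labeling rules are unsatisfiable for a sequence."""


@dataclass
class AnnotatedSp:
    """Input to the labeler: sequence + class + cleavage site + group."""

    sequence: str
    sp_class: SpClass
    cs: int  # 1-based index of the last SP residue
    organism_group: OrganismGroup = OrganismGroup.UNKNOWN
    id: str = ""

    def __post_init__(self) -> None:
        if self.sp_class is SpClass.NO_SP:
            raise ValueError("AnnotatedSp requires an SP class")
        if not 1 <= self.cs < len(self.sequence):
            raise ValueError(
                f"{self.id or 'sequence'}: cs={self.cs} invalid for length "
                f"{len(self.sequence)}"
            )

    @classmethod
    def from_record(cls, record: SequenceRecord) -> "AnnotatedSp":
        if record.cs is None:
            raise ValueError(f"record {record.id} has no cleavage site")
        return cls(
            sequence=record.sequence,
            sp_class=record.sp_class,
            cs=record.cs,
            organism_group=record.organism_group,
            id=record.id,
        )


@dataclass
class MultitagMatrix:
    """Per-position sets of admissible CRF state ids (all of one class)."""

    sets: list[frozenset[int]]
    tag_sets: list[frozenset[str]]
    sp_class: SpClass

    def __len__(self) -> int:
        return len(self.sets)

    def to_strings(self) -> list[str]:
        """Serialize as sorted '+'-joined tag strings, one per position."""
        return ["+".join(sorted(ts)) for ts in self.tag_sets]


def find_h_center(
    sp_seq: str,
    lo: Optional[int] = None,
    hi: Optional[int] = None,
) -> int:
    """1-based center of the most hydrophobic 7-residue window of an SP.

    The returned index is restricted to ``[lo, hi]`` (defaults
    ``[3, L - 3]``) so that the minimum n- and c-region lengths stay
    satisfiable.  Ties break leftmost.  For SPs too short to fit a full
    window inside the admissible range, the single most hydrophobic
    position in the range is returned instead.
    """
    length = len(sp_seq)
    lo = N_MIN + 1 if lo is None else lo
    hi = length - C_MIN if hi is None else hi
    if hi < lo:
        raise LabelingError(
            f"SP of length {length} too short for h-center in [{lo}, {hi}]"
        )
    kd = [kd_value(aa) for aa in sp_seq]

    half = KD_WINDOW // 2
    # centers where the full window fits, intersected with [lo, hi]
    c_lo = max(lo, half + 1)
    c_hi = min(hi, length - half)
    if c_lo <= c_hi:
        best, best_score = None, None
        for center in range(c_lo, c_hi + 1):
            score = sum(kd[center - half - 1: center + half])
            if best_score is None or score > best_score:
                best, best_score = center, score
        return best
    # fallback: single most hydrophobic admissible residue
    best, best_score = None, None
    for center in range(lo, hi + 1):
        if best_score is None or kd[center - 1] > best_score:
            best, best_score = center, kd[center - 1]
    return best


def find_rr_motif(sp_seq: str) -> int:
    """Leftmost admissible twin-arginine dimer start (1-based, >= 3)."""
    for m in range(N_MIN + 1, len(sp_seq)):  # 1-based m, needs m+1 <= L
        if sp_seq[m - 1] == "R" and sp_seq[m] == "R":
            return m
    raise LabelingError("no admissible RR dimer (needs >= 2 n-residues before it)")


def _tagsets_sec_spi(seq: str, cs: int, prefix_tags: Optional[list] = None,
                     h_lo: int = N_MIN + 1) -> list[frozenset[str]]:
    """Shared n/h/c layout; ``prefix_tags`` replaces the leading n-rules
    (used for the Tat variants, where the motif defines the n-region)."""
    if prefix_tags is None:
        if cs < N_MIN + 1 + C_MIN:
            raise LabelingError(f"SP with cs={cs} too short for n>=2, h, c>=3")
        prefix_tags = [frozenset({"N"})] * N_MIN
    i = find_h_center(seq[:cs], lo=h_lo, hi=cs - C_MIN)
    tags = list(prefix_tags)
    if len(tags) > i - 1:
        raise LabelingError(f"h-center {i} overlaps the n-region prefix")
    n_amb = tags[-1] | {"H"}  # {N,H} or {N2,H}
    tags += [n_amb] * (i - 1 - len(tags))
    tags.append(frozenset({"H"}))
    tags += [frozenset({"H", "C"})] * (cs - C_MIN - i)
    tags += [frozenset({"C"})] * C_MIN
    return tags


def _tagsets_sec_spii(seq: str, cs: int, prefix_tags: Optional[list] = None,
                      h_lo: int = N_MIN + 1) -> list[frozenset[str]]:
    """n / ambiguous / h-only block / 3-position lipobox."""
    if prefix_tags is None:
        if cs < N_MIN + 1 + C_MIN:
            raise LabelingError(f"SPII with cs={cs} too short for n>=2, h, lipobox")
        prefix_tags = [frozenset({"N"})] * N_MIN
    i = find_h_center(seq[:cs], lo=h_lo, hi=cs - C_MIN)
    tags = list(prefix_tags)
    if len(tags) > i - 1:
        raise LabelingError(f"h-center {i} overlaps the n-region prefix")
    n_amb = tags[-1] | {"H"}
    tags += [n_amb] * (i - 1 - len(tags))
    tags += [frozenset({"H"})] * (cs - C_MIN - i + 1)
    tags += [frozenset({"L1"}), frozenset({"L2"}), frozenset({"L3"})]
    return tags


def _tat_prefix(seq: str, cs: int) -> tuple[list[frozenset[str]], int]:
    """n1 block, RR motif, single post-motif n2; returns (tags, h_lo)."""
    m = find_rr_motif(seq[:cs])
    tags = [frozenset({"N1"})] * (m - 1)
    tags += [frozenset({"R1"}), frozenset({"R2"})]
    tags += [frozenset({"N2"})]
    return tags, m + 3


def label_regions(sp: AnnotatedSp) -> MultitagMatrix:
    """Apply the per-class labeling rules; mature positions become {O}."""
    seq, cs, sp_class = sp.sequence, sp.cs, sp.sp_class
    try:
        if sp_class is SpClass.SEC_SPI:
            tags = _tagsets_sec_spi(seq, cs)
        elif sp_class is SpClass.SEC_SPII:
            tags = _tagsets_sec_spii(seq, cs)
        elif sp_class is SpClass.SEC_SPIII:
            tags = [frozenset({"P"})] * cs
        elif sp_class is SpClass.TAT_SPI:
            prefix, h_lo = _tat_prefix(seq, cs)
            tags = _tagsets_sec_spi(seq, cs, prefix_tags=prefix, h_lo=h_lo)
        elif sp_class is SpClass.TAT_SPII:
            prefix, h_lo = _tat_prefix(seq, cs)
            tags = _tagsets_sec_spii(seq, cs, prefix_tags=prefix, h_lo=h_lo)
        else:
            raise ValueError(f"not an SP class: {sp_class}")
    except LabelingError as exc:
        raise LabelingError(f"{sp.id or seq[:12]}: {exc}") from None
    assert len(tags) == cs, (len(tags), cs)
    tags = tags + [frozenset({"O"})] * (len(seq) - cs)
    return MultitagMatrix(sets=[], tag_sets=tags, sp_class=sp_class)


def label_no_sp(record: SequenceRecord) -> MultitagMatrix:
    """Singleton I/M/O tags for negatives, from the record annotation."""
    if record.annotation is None:
        ann = "I" * len(record.sequence)
    else:
        ann = record.annotation
    tags = [frozenset({ch}) for ch in ann]
    return MultitagMatrix(sets=[], tag_sets=tags, sp_class=SpClass.NO_SP)


def resolve_state_ids(matrix: MultitagMatrix, space: StateSpace) -> MultitagMatrix:
    """Fill ``sets`` with the state ids of the matrix's class."""
    matrix.sets = [
        frozenset(space.state_id(matrix.sp_class, tag) for tag in ts)
        for ts in matrix.tag_sets
    ]
    return matrix


def label_record(record: SequenceRecord, space: StateSpace) -> MultitagMatrix:
    """Label any record (SP or negative) and resolve state ids."""
    if record.sp_class is SpClass.NO_SP:
        matrix = label_no_sp(record)
    else:
        matrix = label_regions(AnnotatedSp.from_record(record))
    return resolve_state_ids(matrix, space)
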