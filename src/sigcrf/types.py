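"""Shared domain types: classes, organism groups, sequence records."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class SpClass(enum.Enum):
    """The six global sequence classes (five SP types plus no-SP)."""

    NO_SP = "NO_SP"
    SEC_SPI = "SEC_SPI"
    SEC_SPII = "SEC_SPII"
    SEC_SPIII = "SEC_SPIII"
    TAT_SPI = "TAT_SPI"
    TAT_SPII = "TAT_SPII"

    @property
    def is_sp(self) -> bool:
        return self is not SpClass.NO_SP

    @classmethod
    def from_string(cls, s: str) -> "SpClass":
        try:
            return cls[s.upper()]
        except KeyError:
            raise ValueError(f"unknown SP class: {s!r}") from None


SP_CLASSES = [c for c in SpClass if c.is_sp]


class OrganismGroup(enum.Enum):
    ARCHAEA = "ARCHAEA"
    EUKARYA = "EUKARYA"
    GRAM_POS = "GRAM_POS"
    GRAM_NEG = "GRAM_NEG"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def from_string(cls, s: str) -> "OrganismGroup":
        try:
            return cls[s.upper()]
        except KeyError:
            raise ValueError(f"unknown organism group: {s!r}") from None


#: Per-residue annotation characters of the on-disk 3-line format.
#: S = Sec/SPI SP residue, T = Tat SP residue (SPI and SPII share it with
#: the class header disambiguating), L = SPII SP residue, P = SPIII SP
#: residue, I/M/O = intracellular / transmembrane / extracellular mature.
SP_ANNOTATION_CHAR: dict[SpClass, str] = {
    SpClass.SEC_SPI: "S",
    SpClass.TAT_SPI: "T",
    SpClass.SEC_SPII: "L",
    SpClass.TAT_SPII: "L",
    SpClass.SEC_SPIII: "P",
}

MATURE_ANNOTATION_CHARS = "IMO"


@dataclass
class SequenceRecord:
    """One labeled protein sequence.

    ``cs`` is the 1-based index of the last SP residue (cleavage occurs
    between ``cs`` and ``cs + 1``); it is ``None`` for NO_SP records.
    ``annotation`` is the per-residue string over S/T/L/P/I/M/O.
    """

    id: str
    sequence: str
    organism_group: OrganismGroup
    sp_class: SpClass
    cs: Optional[int] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sp_class.is_sp:
            if self.cs is None and self.annotation is not None:
                self.cs = infer_cs_from_annotation(self.annotation)
            if self.cs is not None and not (1 <= self.cs < len(self.sequence)):
                raise ValueError(
                    f"record {self.id}: cs={self.cs} out of range for "
                    f"length {len(self.sequence)}"
                )
        if self.annotation is not None and len(self.annotation) != len(self.sequence):
            raise ValueError(
                f"record {self.id}: annotation length {len(self.annotation)} "
                f"!= sequence length {len(self.sequence)}"
            )


def infer_cs_from_annotation(annotation: str) -> Optional[int]:
    """1-based position of the last SP-tagged residue, or None."""
    last = None
    for i, ch in enumerate(annotation):
        if ch in "STLP":
            last = i + 1
    return last
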