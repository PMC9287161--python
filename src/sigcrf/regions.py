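"""Physicochemical summaries (length, hydrophobicity, charge) of SP
regions called on a decoded path or taken from annotation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .crf import Prediction
from .grammar import StateSpace
from .scales import CHARGE_PH7, KYTE_DOOLITTLE
from .types import OrganismGroup

#: Organism groups whose initiator methionine keeps its free (charged)
#: amino group; in bacteria it is formylated and contributes no charge.
UNFORMYLATED_GROUPS = frozenset(
    {OrganismGroup.EUKARYA, OrganismGroup.ARCHAEA})


@dataclass
class RegionSummary:
    region: str            # region kind: n, h, c, R, l, P
    start: int             # 1-based inclusive
    end: int               # 1-based inclusive
    length: int
    hydrophobicity: float  # mean Kyte-Doolittle
    net_charge: float      # elementary charges at pH 7


def hydrophobicity(region_seq: str) -> float:
    """Mean Kyte-Doolittle value; non-standard residues are excluded."""
    values = [KYTE_DOOLITTLE[aa] for aa in region_seq.upper()
              if aa in KYTE_DOOLITTLE]
    if not values:
        raise ValueError("empty region (or no standard residues)")
    return sum(values) / len(values)


def net_charge(region_seq: str, organism_group: OrganismGroup,
               is_n_terminal: bool = False,
               histidine_charge: float = 0.0) -> float:
    """Summed residue net charges at pH 7.

    K/R contribute +1, D/E -1, H ``histidine_charge`` (0 by default).
    The free amino group of an unformylated initiator methionine adds +1
    when the region is N-terminal and the group is Eukarya or Archaea.
    """
    if not region_seq:
        raise ValueError("empty region")
    total = 0.0
    for aa in region_seq.upper():
        if aa == "H":
            total += histidine_charge
        else:
            total += CHARGE_PH7.get(aa, 0.0)
    if is_n_terminal and organism_group in UNFORMYLATED_GROUPS:
        total += 1.0
    return total


def summarize_regions(prediction: Prediction, sequence: str,
                      organism_group: OrganismGroup,
                      space: StateSpace) -> list[RegionSummary]:
    """One RegionSummary per contiguous SP-region run on the decoded
    path; empty when the path contains no SP states."""
    return summarize_path(
        [space.states[s] for s in prediction.path], sequence, organism_group)


def summarize_path(states: Sequence, sequence: str,
                   organism_group: OrganismGroup) -> list[RegionSummary]:
    runs: list[tuple[str, int, int]] = []  # (kind, start0, end0)
    for i, st in enumerate(states):
        if not st.is_sp_state:
            continue
        kind = st.region_kind
        if runs and runs[-1][0] == kind and runs[-1][2] == i - 1:
            runs[-1] = (kind, runs[-1][1], i)
        else:
            runs.append((kind, i, i))
    out = []
    for kind, s0, e0 in runs:
        seq = sequence[s0:e0 + 1]
        out.append(RegionSummary(
            region=kind, start=s0 + 1, end=e0 + 1, length=e0 - s0 + 1,
            hydrophobicity=hydrophobicity(seq),
            net_charge=net_charge(seq, organism_group,
                                  is_n_terminal=(s0 == 0)),
        ))
    return out
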