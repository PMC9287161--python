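"""CRF state space and the region-order transition grammar.

Each of the six global classes owns a private copy of every state it can
visit, including the mature-protein states (I, M, O), so that each CRF
state maps to exactly one class and summed marginals over a class are a
proper probability.  Transitions never cross classes; within an SP class
they enforce the region order (n before h before c, fixed-length RR and
lipobox motifs, undifferentiated P for SPIII).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SpClass

#: Region tags.  N1/N2 are the pre-/post-motif n-segments of Tat SPs.
SP_TAGS = ("N", "N1", "N2", "H", "C", "R1", "R2", "L1", "L2", "L3", "P")
MATURE_TAGS = ("O", "M", "I")

#: tag -> region kind used for pooling across classes ('n', 'h', 'c',
#: 'R' twin-arginine, 'l' lipobox, 'P' undifferentiated SPIII).
REGION_KIND = {
    "N": "n", "N1": "n", "N2": "n",
    "H": "h",
    "C": "c",
    "R1": "R", "R2": "R",
    "L1": "l", "L2": "l", "L3": "l",
    "P": "P",
    "O": "O", "M": "M", "I": "I",
}

# Ordered tag inventory per class: SP tags first (in region order), then
# the mature tags entered after cleavage (or carrying the whole sequence
# for NO_SP).
_CLASS_TAGS: dict[SpClass, tuple[str, ...]] = {
    SpClass.NO_SP: ("I", "M", "O"),
    SpClass.SEC_SPI: ("N", "H", "C", "O", "M", "I"),
    SpClass.SEC_SPII: ("N", "H", "L1", "L2", "L3", "O", "M", "I"),
    SpClass.SEC_SPIII: ("P", "O", "M", "I"),
    SpClass.TAT_SPI: ("N1", "R1", "R2", "N2", "H", "C", "O", "M", "I"),
    SpClass.TAT_SPII: ("N1", "R1", "R2", "N2", "H", "L1", "L2", "L3", "O", "M", "I"),
}

# Within-class SP-region transitions (tag -> allowed successor tags).
# The final SP tag of each class additionally transitions into "O".
_SP_TRANSITIONS: dict[SpClass, dict[str, tuple[str, ...]]] = {
    SpClass.NO_SP: {},
    SpClass.SEC_SPI: {
        "N": ("N", "H"), "H": ("H", "C"), "C": ("C", "O"),
    },
    SpClass.SEC_SPII: {
        "N": ("N", "H"), "H": ("H", "L1"), "L1": ("L2",), "L2": ("L3",),
        "L3": ("O",),
    },
    SpClass.SEC_SPIII: {"P": ("P", "O")},
    SpClass.TAT_SPI: {
        "N1": ("N1", "R1"), "R1": ("R2",), "R2": ("N2",),
        "N2": ("N2", "H"), "H": ("H", "C"), "C": ("C", "O"),
    },
    SpClass.TAT_SPII: {
        "N1": ("N1", "R1"), "R1": ("R2",), "R2": ("N2",),
        "N2": ("N2", "H"), "H": ("H", "L1"), "L1": ("L2",), "L2": ("L3",),
        "L3": ("O",),
    },
}

# Mature-region topology shared by every class.
_MATURE_TRANSITIONS = {
    "O": ("O", "M"),
    "M": ("M", "I", "O"),
    "I": ("I", "M"),
}

#: First SP state of each SP class (the only allowed start state there).
FIRST_SP_TAG: dict[SpClass, str] = {
    SpClass.SEC_SPI: "N",
    SpClass.SEC_SPII: "N",
    SpClass.SEC_SPIII: "P",
    SpClass.TAT_SPI: "N1",
    SpClass.TAT_SPII: "N1",
}


@dataclass(frozen=True)
class LabelState:
    id: int
    sp_class: SpClass
    tag: str
    is_sp_state: bool

    @property
    def region_kind(self) -> str:
        return REGION_KIND[self.tag]


@dataclass
class StateSpace:
    """State inventory plus the boolean transition/start/end masks."""

    states: list[LabelState]
    allowed: np.ndarray        # (C, C) bool, allowed[i, j]: i -> j permitted
    start_allowed: np.ndarray  # (C,) bool
    end_allowed: np.ndarray    # (C,) bool
    _by_class: dict[SpClass, list[LabelState]] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def states_of_class(self, sp_class: SpClass) -> list[LabelState]:
        if sp_class not in self._by_class:
            raise ValueError(f"unknown class: {sp_class!r}")
        return list(self._by_class[sp_class])

    def state_ids_of_class(self, sp_class: SpClass) -> list[int]:
        return [s.id for s in self.states_of_class(sp_class)]

    @property
    def class_of_state(self) -> np.ndarray:
        """Index into ``list(SpClass)`` for each state."""
        order = {c: i for i, c in enumerate(SpClass)}
        return np.array([order[s.sp_class] for s in self.states])

    @property
    def sp_state_mask(self) -> np.ndarray:
        return np.array([s.is_sp_state for s in self.states])

    def state_id(self, sp_class: SpClass, tag: str) -> int:
        for s in self._by_class[sp_class]:
            if s.tag == tag:
                return s.id
        raise KeyError(f"no state {tag!r} in class {sp_class}")

    def region_kind_mask(self, kind: str) -> np.ndarray:
        """Boolean mask of states whose tag pools into region ``kind``."""
        return np.array([s.region_kind == kind for s in self.states])

    def to_table(self) -> str:
        """Plain-text adjacency table for inspection."""
        lines = ["# id\tclass\ttag\tstart\tend\tsuccessors"]
        for s in self.states:
            succ = [
                f"{t.sp_class.value}.{t.tag}"
                for t in self.states
                if self.allowed[s.id, t.id]
            ]
            lines.append(
                "\t".join([
                    str(s.id), s.sp_class.value, s.tag,
                    "1" if self.start_allowed[s.id] else "0",
                    "1" if self.end_allowed[s.id] else "0",
                    ",".join(succ),
                ])
            )
        return "\n".join(lines) + "\n"


def build_state_space() -> StateSpace:
    """Construct the canonical 41-state grammar."""
    states: list[LabelState] = []
    by_class: dict[SpClass, list[LabelState]] = {c: [] for c in SpClass}
    for sp_class in SpClass:
        for tag in _CLASS_TAGS[sp_class]:
            st = LabelState(
                id=len(states),
                sp_class=sp_class,
                tag=tag,
                is_sp_state=tag in SP_TAGS,
            )
            states.append(st)
            by_class[sp_class].append(st)

    c = len(states)
    allowed = np.zeros((c, c), dtype=bool)
    start = np.zeros(c, dtype=bool)
    end = np.zeros(c, dtype=bool)

    def sid(sp_class: SpClass, tag: str) -> int:
        for s in by_class[sp_class]:
            if s.tag == tag:
                return s.id
        raise KeyError((sp_class, tag))

    for sp_class in SpClass:
        trans = dict(_SP_TRANSITIONS[sp_class])
        for tag, succs in _MATURE_TRANSITIONS.items():
            trans[tag] = succs
        for tag, succs in trans.items():
            for succ in succs:
                allowed[sid(sp_class, tag), sid(sp_class, succ)] = True
        # mature states terminate any sequence
        for tag in MATURE_TAGS:
            end[sid(sp_class, tag)] = True
        if sp_class is SpClass.NO_SP:
            for tag in MATURE_TAGS:
                start[sid(sp_class, tag)] = True
        else:
            start[sid(sp_class, FIRST_SP_TAG[sp_class])] = True

    space = StateSpace(
        states=states, allowed=allowed, start_allowed=start, end_allowed=end,
    )
    space._by_class = by_class
    return space


def states_of_class(space: StateSpace, sp_class: SpClass) -> list[LabelState]:
    """Free-function alias for :meth:`StateSpace.states_of_class`."""
    return space.states_of_class(sp_class)
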