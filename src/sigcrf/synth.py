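"""Synthetic labeled datasets with the compositional structure of the
five SP types plus soluble/transmembrane negatives.

The composition tables are free inventions tuned so that a small encoder
can learn the classes; they are configuration, not claims about real
signal peptide statistics.  Every generated SP record is constructed to
be feasible under the region-labeling rules (motifs in admissible
positions, minimum region lengths respected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .scales import AMINO_ACIDS
from .types import OrganismGroup, SequenceRecord, SpClass, SP_ANNOTATION_CHAR

# ---------------------------------------------------------------- tables

N_REGION = {"K": 0.30, "R": 0.20, "N": 0.10, "S": 0.10, "T": 0.10,
            "A": 0.10, "Q": 0.10}
H_REGION = {"L": 0.35, "A": 0.15, "V": 0.15, "I": 0.15, "F": 0.10,
            "W": 0.05, "M": 0.05}
C_REGION = {"A": 0.30, "S": 0.20, "G": 0.15, "T": 0.15, "Q": 0.10,
            "P": 0.10}
SPIII_SP = {"K": 0.20, "Q": 0.15, "E": 0.15, "G": 0.15, "A": 0.10,
            "N": 0.10, "R": 0.10, "S": 0.05}
BACKGROUND = {"A": 0.08, "C": 0.01, "D": 0.06, "E": 0.07, "F": 0.03,
              "G": 0.07, "H": 0.02, "I": 0.04, "K": 0.07, "L": 0.07,
              "M": 0.02, "N": 0.05, "P": 0.05, "Q": 0.05, "R": 0.06,
              "S": 0.08, "T": 0.06, "V": 0.05, "W": 0.01, "Y": 0.04}

DEFAULT_GROUP_PROPORTIONS = {
    OrganismGroup.EUKARYA: 0.40,
    OrganismGroup.GRAM_NEG: 0.25,
    OrganismGroup.GRAM_POS: 0.25,
    OrganismGroup.ARCHAEA: 0.10,
}

DEFAULT_TRAIN_COUNTS = {
    SpClass.SEC_SPI: 150, SpClass.SEC_SPII: 100, SpClass.SEC_SPIII: 50,
    SpClass.TAT_SPI: 75, SpClass.TAT_SPII: 50, SpClass.NO_SP: 175,
}
DEFAULT_TEST_COUNTS = {
    SpClass.SEC_SPI: 50, SpClass.SEC_SPII: 33, SpClass.SEC_SPIII: 17,
    SpClass.TAT_SPI: 25, SpClass.TAT_SPII: 17, SpClass.NO_SP: 58,
}


@dataclass
class GeneratorConfig:
    counts: dict = field(default_factory=lambda: dict(DEFAULT_TRAIN_COUNTS))
    group_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    n_len: tuple[int, int] = (2, 8)        # SPI/SPII n-region
    n1_len: tuple[int, int] = (2, 5)       # Tat pre-motif n
    n2_len: tuple[int, int] = (1, 4)       # Tat post-motif n
    h_len: tuple[int, int] = (7, 15)
    c_len: tuple[int, int] = (3, 7)
    spiii_len: tuple[int, int] = (8, 18)
    mature_len: tuple[int, int] = (20, 40)
    tm_len: tuple[int, int] = (16, 22)
    tm_fraction: float = 0.4               # fraction of negatives with a TM
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if self.n_len[1] < 2 or self.n_len[0] < 2:
            raise ValueError("n-region length must allow the minimum of 2")
        if self.c_len[0] < 3:
            raise ValueError("c-region length must allow the minimum of 3")


def _sample(rng: np.random.Generator, table: dict, k: int) -> str:
    letters = sorted(table)
    probs = np.array([table[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=k, p=probs))


def _rand_len(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _sample_group(rng: np.random.Generator, proportions: dict) -> OrganismGroup:
    groups = sorted(proportions, key=lambda g: g.value)
    probs = np.array([proportions[g] for g in groups])
    probs = probs / probs.sum()
    return groups[int(rng.choice(len(groups), p=probs))]


def _make_sp_parts(rng: np.random.Generator, sp_class: SpClass,
                   cfg: GeneratorConfig) -> tuple[str, str]:
    """Return (sp_sequence, mature_sequence) for one SP record."""
    mature = _sample(rng, BACKGROUND, _rand_len(rng, cfg.mature_len))
    if sp_class is SpClass.SEC_SPIII:
        sp = _sample(rng, SPIII_SP, _rand_len(rng, cfg.spiii_len) - 1) + "G"
        sp = "M" + sp[1:]
        # pilin-like hydrophobic start of the mature protein
        mature = _sample(rng, H_REGION, 8) + mature[8:]
        mature = "F" + mature[1:]
        return sp, mature

    if sp_class in (SpClass.TAT_SPI, SpClass.TAT_SPII):
        n_part = ("M" + _sample(rng, N_REGION, _rand_len(rng, cfg.n1_len) - 1)
                  + "RR" + _sample(rng, N_REGION, _rand_len(rng, cfg.n2_len)))
    else:
        n_part = "M" + _sample(rng, N_REGION, _rand_len(rng, cfg.n_len) - 1)
    h_part = _sample(rng, H_REGION, _rand_len(rng, cfg.h_len))

    if sp_class in (SpClass.SEC_SPII, SpClass.TAT_SPII):
        lipobox = "L" + rng.choice(list("AS")) + rng.choice(list("AG"))
        mature = "C" + mature[1:]
        return n_part + h_part + lipobox, mature
    # SPI-type polar c-region with an A-x-A motif before the CS
    c_part = list(_sample(rng, C_REGION, _rand_len(rng, cfg.c_len)))
    c_part[-3], c_part[-1] = "A", "A"
    return n_part + h_part + "".join(c_part), mature


def _make_negative(rng: np.random.Generator, cfg: GeneratorConfig,
                   transmembrane: bool) -> tuple[str, str]:
    """Return (sequence, annotation) for a NO_SP record."""
    if not transmembrane:
        seq = _sample(rng, BACKGROUND, _rand_len(rng, cfg.mature_len) + 15)
        return seq, "I" * len(seq)
    pre = _sample(rng, BACKGROUND, int(rng.integers(6, 14)))
    tm = _sample(rng, H_REGION, _rand_len(rng, cfg.tm_len))
    post = _sample(rng, BACKGROUND, int(rng.integers(10, 25)))
    seq = pre + tm + post
    ann = "I" * len(pre) + "M" * len(tm) + "O" * len(post)
    return seq, ann


def generate(config: GeneratorConfig) -> list[SequenceRecord]:
    """Generate a labeled dataset; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    for sp_class in SpClass:  # fixed iteration order for determinism
        count = config.counts.get(sp_class, 0)
        for i in range(count):
            group = _sample_group(rng, config.group_proportions)
            rid = f"{sp_class.value}_{i:04d}"
            if sp_class is SpClass.NO_SP:
                is_tm = rng.random() < config.tm_fraction
                seq, ann = _make_negative(rng, config, is_tm)
                records.append(SequenceRecord(
                    id=rid, sequence=seq, organism_group=group,
                    sp_class=sp_class, cs=None, annotation=ann))
            else:
                sp, mature = _make_sp_parts(rng, sp_class, config)
                seq = sp + mature
                ann = (SP_ANNOTATION_CHAR[sp_class] * len(sp)
                       + "O" * len(mature))
                records.append(SequenceRecord(
                    id=rid, sequence=seq, organism_group=group,
                    sp_class=sp_class, cs=len(sp), annotation=ann))
    return records


# ------------------------------------------------- homology-family fixture

def _protected_positions(record: SequenceRecord) -> set[int]:
    """0-based positions whose mutation could break labeling feasibility."""
    protected = {0}
    cs = record.cs
    if cs is None:
        return protected
    seq = record.sequence
    if record.sp_class in (SpClass.TAT_SPI, SpClass.TAT_SPII):
        for m in range(2, cs - 1):
            if seq[m] == "R" and seq[m + 1] == "R":
                protected |= {m, m + 1}
                break
    if record.sp_class in (SpClass.SEC_SPII, SpClass.TAT_SPII):
        protected |= {cs - 3, cs - 2, cs - 1, cs}  # lipobox + lipidated C
    elif record.sp_class is not SpClass.SEC_SPIII:
        protected |= {cs - 3, cs - 1}              # A-x-A anchors
    return protected


def generate_homology_families(
    config: GeneratorConfig,
    n_families: int,
    mutation_rate: float,
    n_members: int = 5,
    classes: Optional[list[SpClass]] = None,
) -> list[SequenceRecord]:
    """Families of point-mutated copies of seed records.

    Within-family identity is ~(1 - mutation_rate); between-family
    identity is that of unrelated random sequences, far below typical
    partitioning thresholds.  Mutations are substitutions only, so the
    cleavage site and annotation carry over, and positions that anchor
    labeling-rule motifs are never mutated.
    """
    if not 0.0 < mutation_rate < 1.0:
        raise ValueError("mutation_rate must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    classes = classes if classes is not None else [c for c in SpClass]
    letters = list(AMINO_ACIDS)
    out: list[SequenceRecord] = []
    for fam in range(n_families):
        sp_class = classes[fam % len(classes)]
        seed_cfg = replace(config, counts={sp_class: 1},
                           seed=int(rng.integers(0, 2**31)))
        seed_rec = generate(seed_cfg)[0]
        protected = _protected_positions(seed_rec)
        for member in range(n_members):
            if member == 0:
                seq = seed_rec.sequence
            else:
                chars = list(seed_rec.sequence)
                for pos in range(len(chars)):
                    if pos in protected:
                        continue
                    if rng.random() < mutation_rate:
                        alternatives = [a for a in letters if a != chars[pos]]
                        chars[pos] = alternatives[int(rng.integers(19))]
                seq = "".join(chars)
            out.append(SequenceRecord(
                id=f"fam{fam:02d}_m{member}",
                sequence=seq,
                organism_group=seed_rec.organism_group,
                sp_class=sp_class,
                cs=seed_rec.cs,
                annotation=seed_rec.annotation,
            ))
    return out
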