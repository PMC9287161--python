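"""Per-residue physicochemical constants.

The hydropathy values are the standard Kyte-Doolittle table; the charge
table holds net side-chain charges at pH 7 (histidine treated as neutral
by default, configurable at the call sites that use it).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Net charge at pH 7 per residue (elementary charges).
CHARGE_PH7: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE_PH7.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})

#: Residues outside the standard alphabet map to an UNK token.
NONSTANDARD: str = "BZXUO"


def kd_value(residue: str) -> float:
    """Kyte-Doolittle value of a single residue; 0.0 for non-standard."""
    return KYTE_DOOLITTLE.get(residue, 0.0)
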