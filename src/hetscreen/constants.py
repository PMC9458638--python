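"""Shared amino-acid reference data.

Two small tables are used throughout the package:

* ``BACKGROUND_FREQS`` — background amino-acid frequencies (Robinson &
  Robinson, PNAS 1991), used as the prior for alignment-profile
  pseudocounts and as the default residue composition of the synthetic
  generators.
* ``MAX_ASA_GXG`` — maximal solvent accessibility of residue X in an
  extended Gly-X-Gly tripeptide, in Å² (theoretical values of Tien et
  al., PLoS ONE 2013).  Burial is defined as this reference minus the
  observed accessibility, so a fully exposed residue has burial 0.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Robinson & Robinson (1991) composition, renormalised over the 20
# standard residues.
_RR = {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0193,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0224, "F": 0.0385, "P": 0.0520,
    "S": 0.0711, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644,
}
_total = sum(_RR.values())
BACKGROUND_FREQS: dict[str, float] = {aa: _RR[aa] / _total for aa in AMINO_ACIDS}

BACKGROUND_VECTOR: np.ndarray = np.array(
    [BACKGROUND_FREQS[aa] for aa in AMINO_ACIDS]
)

# Theoretical Gly-X-Gly maximal accessibilities (Tien et al. 2013), Å².
MAX_ASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Residues treated as hydrophobic by the synthetic residue-feature
# generator (they are planted with lower accessibility on average).
HYDROPHOBIC: frozenset[str] = frozenset("AVLIMFWC")
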