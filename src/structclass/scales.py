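"""Amino-acid alphabets and residue property scales.

The PSSM column order is the PSI-BLAST header order; every per-column
feature in :mod:`structclass.features` uses this ordering.
"""

from __future__ import annotations

import numpy as np

#: PSI-BLAST log-odds column order (A R N D C Q E G H I L K M F P S T W Y V).
PSSM_COLUMNS: str = "ARNDCQEGHILKMFPSTWYV"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Average side-chain masses in Daltons (residue mass minus the Gly backbone).
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.03, "R": 100.14, "N": 58.06, "D": 59.04, "C": 47.10,
    "Q": 72.09, "E": 73.07, "G": 1.01, "H": 81.10, "I": 57.11,
    "L": 57.11, "K": 72.13, "M": 75.15, "F": 91.13, "P": 42.08,
    "S": 31.03, "T": 45.04, "W": 130.17, "Y": 107.13, "V": 43.09,
}


def scale_vector(scale: dict[str, float]) -> np.ndarray:
    """Return a scale as a length-20 vector in PSSM column order."""
    missing = [a for a in PSSM_COLUMNS if a not in scale]
    if missing:
        raise ValueError(f"scale is missing amino acids: {missing}")
    return np.array([scale[a] for a in PSSM_COLUMNS], dtype=float)
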