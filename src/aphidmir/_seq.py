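"""Small nucleotide-string helpers shared across modules.

All genomic coordinates in this package are 0-based half-open; RNA (U) and
DNA (T) spellings are accepted interchangeably at every public entry point.
"""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

DNA_ALPHABET = "ACGT"


def to_dna(seq: str) -> str:
    """Uppercase and spell in DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and spell in RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return to_dna(seq).translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_RNA_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform-composition random DNA string."""
    if length <= 0:
        return ""
    idx = rng.integers(0, 4, size=length)
    lut = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    return lut[idx].tobytes().decode()
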