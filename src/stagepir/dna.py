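"""Small DNA helpers shared across the package.

Reads are handled in the DNA alphabet (ACGT); uracil shown in reports is a
display convention for T.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: uint8 byte codes for the bases, used by vectorised genome scans
A, C, G, T = 65, 67, 71, 84

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True) -> None:
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def as_bytes(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
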