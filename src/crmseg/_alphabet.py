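"""DNA alphabet helpers shared across the package.

Sequences are handled internally as integer code arrays over A=0, C=1, G=2,
T=3; the ambiguity code N is carried as 4 and emitted with probability 1/4 by
every state.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = N_CODE
_CODE[ord("n")] = N_CODE

# IUPAC ambiguity codes other than N are accepted on input but collapsed to N.
for _b in "RYSWKMBDHV":
    _CODE[ord(_b)] = N_CODE
    _CODE[ord(_b.lower())] = N_CODE


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3, ambiguous=4).

    Raises ValueError naming the offending offset for non-IUPAC characters.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        off = int(bad[0])
        raise ValueError(
            f"non-IUPAC character {sequence[off]!r} at offset {off}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement integer codes; N stays N."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out.astype(codes.dtype)


def reverse_complement(sequence: str) -> str:
    return decode(complement_codes(encode(sequence))[::-1])
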