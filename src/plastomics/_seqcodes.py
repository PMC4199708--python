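"""Byte-level DNA encoding shared by the search kernels.

Unambiguous bases map to 0..3 (A,C,G,T) so that the complement of a code
``x`` is ``3 - x``. Alignment gaps map to GAP, every IUPAC ambiguity code
(including N) to AMBIG. Ambiguous bases never match anything, themselves
included — a deliberate, conservative choice that keeps N-runs from
seeding spurious repeat hits.
"""

from __future__ import annotations

import numpy as np

AMBIG = np.uint8(255)
GAP = np.uint8(254)

_LUT = np.full(256, AMBIG, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _LUT[ord(base)] = i
    _LUT[ord(base.lower())] = i
_LUT[ord("-")] = GAP
_LUT[ord(".")] = GAP

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _DECODE[i] = ord(base)
_DECODE[GAP] = ord("-")

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; ambiguity/gap codes are preserved."""
    out = codes[::-1].copy()
    plain = out < 4
    out[plain] = 3 - out[plain]
    return out


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC-aware."""
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def is_valid_dna(seq: str) -> bool:
    allowed = set("ACGTRYSWKMBVDHN-.")
    return all(b in allowed for b in seq.upper())
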