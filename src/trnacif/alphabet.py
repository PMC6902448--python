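"""Alphabets shared across the toolkit.

Functional classes are the 20 elongator isoacceptor families named by
one-letter amino-acid symbols, plus the initiator tRNA-fMet class ("X")
and the tRNA-Ile(CAU) class ("J"): 22 classes in total.
"""

from __future__ import annotations

import numpy as np

#: RNA bases over which features are defined, in canonical storage order.
BASES: str = "ACGU"

#: Gap symbol used in aligned sequences.
GAP: str = "-"

#: The 22 tRNA functional classes: elongator isotypes + initiator X + Ile-CAU J.
CLASSES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + ("X", "J")

CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Integer codes: bases 0..3, gap 4. Ambiguity codes collapse to gap because
#: features are defined only over {A, C, G, U}.
GAP_CODE: int = 4

_AMBIGUITY = "RYSWKMBDHVN"

# byte -> code lookup (256 entries); 255 marks an invalid symbol
ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ENCODE_LUT[ord(_b)] = _i
ENCODE_LUT[ord(GAP)] = GAP_CODE
ENCODE_LUT[ord(".")] = GAP_CODE
for _a in _AMBIGUITY:
    ENCODE_LUT[ord(_a)] = GAP_CODE


def normalize_sequence(seq: str) -> str:
    """Fold case, convert DNA T to RNA U, and map ambiguity codes to gaps.

    Raises ``ValueError`` naming the first offending column when a symbol
    is not a base, gap, or IUPAC ambiguity code.
    """
    s = seq.upper().replace("T", "U").replace(".", GAP)
    for amb in _AMBIGUITY:
        if amb in s:
            s = s.replace(amb, GAP)
    for col, ch in enumerate(s):
        if ch not in "ACGU" + GAP:
            raise ValueError(f"unknown residue symbol {ch!r} at column {col}")
    return s


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a normalized aligned sequence to uint8 codes (A=0..U=3, gap=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = ENCODE_LUT[raw]
    if (codes == 255).any():
        col = int(np.argmax(codes == 255))
        raise ValueError(f"unknown residue symbol {seq[col]!r} at column {col}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    table = BASES + GAP
    return "".join(table[c] for c in codes)
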