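"""IUPAC nucleotide codes as 4-bit masks.

Every degenerate symbol is the bitwise OR of the bases it expands to
(A=1, C=2, G=4, T=8).  Two symbols are *compatible* — a primer base can
pair with a template base — iff their masks intersect.  Gap ('-') carries
mask 0 and is therefore incompatible with everything.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

#: symbol -> bitmask over {A,C,G,T}
CODE_TO_MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": A | C | G | T,
    "-": 0,
}

MASK_TO_CODE: dict[int, str] = {m: s for s, m in CODE_TO_MASK.items() if s != "-"}

IUPAC_CODES = frozenset(MASK_TO_CODE.values())
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)

# 256-entry lookup for fast text -> mask encoding
_ENC = np.zeros(256, dtype=np.uint8)
for _sym, _mask in CODE_TO_MASK.items():
    _ENC[ord(_sym)] = _mask
    _ENC[ord(_sym.lower())] = _mask


def expand(symbol: str) -> frozenset[str]:
    """Set of unambiguous bases an IUPAC symbol stands for."""
    try:
        mask = CODE_TO_MASK[symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {symbol!r}") from None
    return frozenset(b for b in "ACGT" if CODE_TO_MASK[b] & mask)


def code_for(bases: frozenset[str] | set[str]) -> str:
    """The unique IUPAC symbol whose expansion is exactly `bases`."""
    mask = 0
    for b in bases:
        if b not in UNAMBIGUOUS:
            raise ValueError(f"not an unambiguous base: {b!r}")
        mask |= CODE_TO_MASK[b]
    if mask == 0:
        raise ValueError("empty base set has no IUPAC code")
    return MASK_TO_CODE[mask]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 mask array; unknown symbols become 0."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENC[arr]
    bad = (out == 0) & (arr != ord("-"))
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(f"invalid nucleotide symbol {seq[pos]!r} at position {pos}")
    return out


def is_unambiguous(seq: str) -> bool:
    return all(ch in UNAMBIGUOUS for ch in seq)
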