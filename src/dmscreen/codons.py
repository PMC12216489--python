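"""Codon/amino-acid alphabets and fast base-level encodings.

All sequence simulation and consensus calling works on uint8 base codes
(A=0, C=1, G=2, T=3); codon indices are the base-4 value of the triplet,
which coincides with the lexicographic order of :data:`CODONS`.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"

#: All 64 DNA triplets in lexicographic (ACGT) order.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Standard-table translation of every codon ('*' for stop).
CODON_TO_AA: dict[str, str] = {c: str(Seq(c).translate()) for c in CODONS}

STOP_AA = "*"
STOP_CODONS: frozenset[str] = frozenset(c for c, a in CODON_TO_AA.items() if a == STOP_AA)

#: The 20 standard amino acids, alphabetical.
AA_ALPHABET: tuple[str, ...] = tuple(sorted({a for a in CODON_TO_AA.values() if a != STOP_AA}))

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Per-codon amino-acid index into AA_ALPHABET, or -1 for stop codons.
CODON_AA_IDX: np.ndarray = np.array(
    [AA_INDEX.get(CODON_TO_AA[c], -1) for c in CODONS], dtype=np.int64
)

# byte <-> code lookup tables; anything that is not ACGT encodes to 4.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 base codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_seq(codes: np.ndarray) -> str:
    """Decode uint8 base codes back to a DNA string."""
    return _DECODE_LUT[np.minimum(codes, 4)].tobytes().decode("ascii")


def codon_index(codon: str) -> int:
    """Index of ``codon`` in :data:`CODONS`; raises for invalid triplets."""
    try:
        return CODON_INDEX[codon.upper()]
    except KeyError:
        raise ValueError(f"not a valid DNA codon: {codon!r}") from None


def translate_codons(codons: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Translate a codon sequence to a per-site amino-acid tuple ('*' = stop)."""
    return tuple(CODON_TO_AA[c] for c in codons)


def is_valid_codon(codon: str) -> bool:
    return codon.upper() in CODON_INDEX
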