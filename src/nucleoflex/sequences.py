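"""Low-level DNA sequence utilities.

Encoding convention: A=0, C=1, G=2, T=3, anything ambiguous (N, ...) = 4.
All genomic coordinates in the package are 0-based half-open; a "cut
position" i denotes the inter-base bond immediately 5' of base i, so the
tetramer spanning a cut is ``seq[i-2:i+2]``.

Tetramers are collapsed with their reverse complements into 136 canonical
pairs labelled ``"ABCD.WXYZ"`` with the lexicographically smaller member
first (palindromic tetramers pair with themselves, e.g. ``"CTAG.CTAG"``).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidSequenceError

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# str -> uint8 translation table (A0 C1 G2 T3, other -> 4)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

N_PAIRS = 136  # canonical reverse-complement-collapsed tetramer pairs


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed, case-folded)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise InvalidSequenceError(f"non-DNA character {exc.args[0]!r}") from exc


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (ambiguous bases become 4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def dinucleotide_codes(codes: np.ndarray) -> np.ndarray:
    """Per-step dinucleotide codes (0..15) for a coded sequence.

    Length is ``len(codes) - 1``; steps touching an ambiguous base get -1.
    """
    a, b = codes[:-1].astype(np.int64), codes[1:].astype(np.int64)
    out = 4 * a + b
    out[(a > 3) | (b > 3)] = -1
    return out


def tetramer_codes(codes: np.ndarray) -> np.ndarray:
    """Codes (0..255) of every overlapping 4-mer; -1 where any base is ambiguous.

    Length is ``len(codes) - 3``; entry i covers ``seq[i:i+4]``.
    """
    c = codes.astype(np.int64)
    out = 64 * c[:-3] + 16 * c[1:-2] + 4 * c[2:-1] + c[3:]
    bad = (c[:-3] > 3) | (c[1:-2] > 3) | (c[2:-1] > 3) | (c[3:] > 3)
    out[bad] = -1
    return out


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def _build_pair_tables():
    canon_of = np.empty(256, dtype=np.int64)   # tetramer code -> pair index
    rc_code = np.empty(256, dtype=np.int64)    # tetramer code -> revcomp code
    labels: list[str] = []
    canon_codes: list[int] = []
    seen: dict[int, int] = {}
    for code in range(256):
        rc = _revcomp_code(code, 4)
        rc_code[code] = rc
        canon = min(code, rc)
        if canon not in seen:
            seen[canon] = len(labels)
            labels.append(f"{_decode_kmer(canon, 4)}.{_decode_kmer(max(code, rc), 4)}")
            canon_codes.append(canon)
        canon_of[code] = seen[canon]
    order = np.argsort(np.array(labels))
    remap = np.empty(len(labels), dtype=np.int64)
    remap[order] = np.arange(len(labels))
    return remap[canon_of], rc_code, [labels[i] for i in order], [canon_codes[i] for i in order]


PAIR_INDEX_OF_CODE, REVCOMP_CODE, PAIR_LABELS, PAIR_CANONICAL_CODES = _build_pair_tables()
assert len(PAIR_LABELS) == N_PAIRS


def canonical_context(context: str):
    """Canonicalize a dinucleotide or tetramer sequence context.

    Returns ``(canonical, reversed_flag)`` where ``canonical`` is the
    lexicographic minimum of the context and its reverse complement and
    ``reversed_flag`` is True iff the reverse complement was chosen.  When
    the flag is set, equilibrium helical parameters looked up under the
    canonical form must be read with shift and tilt sign-flipped (strand
    symmetry of base-step parameters).
    """
    context = context.upper()
    if len(context) not in (2, 4):
        raise InvalidSequenceError(f"context must have length 2 or 4, got {context!r}")
    if any(b not in BASES for b in context):
        raise InvalidSequenceError(f"non-ACGT character in context {context!r}")
    rc = reverse_complement(context)
    if rc < context:
        return rc, True
    return context, False


def pair_label(tetramer: str) -> str:
    """Canonical ``"ABCD.WXYZ"`` label for a tetramer."""
    canon, _ = canonical_context(tetramer)
    if len(canon) != 4:
        raise InvalidSequenceError("pair labels are defined for tetramers")
    return f"{canon}.{reverse_complement(canon)}"
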