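"""Base-4 k-mer codes, reverse complements and canonical forms.

A k-mer over {A, C, G, T} is encoded as an integer in base 4 with
A=0, C=1, G=2, T=3 and the leftmost base most significant, so codes
range over [0, 4**k).  k is capped at 16 so every code fits a uint64
and a whole-genome presence bit-array stays below 512 MiB.
"""

from __future__ import annotations

MAX_K = 16

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class AmbiguousBaseError(ValueError):
    """Sequence contains a base outside {A, C, G, T} (e.g. N)."""


def _validate(seq: str) -> str:
    s = seq.upper()
    for ch in s:
        if ch not in _BASE_TO_CODE:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in {seq!r}")
    return s


def encode_kmer(seq: str) -> int:
    """Encode an ACGT string of length 1..16 as its base-4 integer code."""
    if not 1 <= len(seq) <= MAX_K:
        raise ValueError(f"k-mer length must be in [1, {MAX_K}], got {len(seq)}")
    code = 0
    for ch in _validate(seq):
        code = (code << 2) | _BASE_TO_CODE[ch]
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a given k."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_TO_BASE[(code >> shift) & 3])
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse-complement an ACGT string; an involution."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def canonical_form(seq: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement.

    Strand-equivalent k-mers share one canonical representative, which is
    how emerged nullomers are deduplicated throughout the package.
    """
    s = _validate(seq)
    rc = s.translate(_COMPLEMENT)[::-1]
    return s if s <= rc else rc
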