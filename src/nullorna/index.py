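"""Presence/absence universe of all k-mers of a genome.

The index answers "does this k-mer occur anywhere in the genome, on
either strand?" in O(1) via a flat bit-array of 4**k bits.  A nullomer
is a k-mer whose presence bit is unset.  Because both strands are
indexed, the presence set (and hence the nullomer set) is closed under
reverse complement.
"""

from __future__ import annotations

import struct
from collections.abc import Iterator, Mapping

import numpy as np

from .kmers import (
    MAX_K,
    AmbiguousBaseError,
    decode_kmer,
    encode_kmer,
    reverse_complement,
)

_MAGIC = b"NIX1"

# base -> 2-bit code lookup; 4 marks an ambiguous character
_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _LUT[_b] = _c
for _b, _c in zip(b"acgt", range(4)):
    _LUT[_b] = _c

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.uint32)


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Codes of every length-k window of ``seq`` free of ambiguous bases."""
    vals = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if vals.size < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = (win != 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    codes = (win[valid].astype(np.uint64) * powers).sum(axis=1)
    return codes


class NullomerIndex:
    """Bit-packed presence of every k-mer of a genome, both strands.

    Parameters
    ----------
    k : int
        K-mer length, 1..16.
    bits : numpy.ndarray of uint8
        Packed presence bits, little-endian within each byte
        (bit ``code & 7`` of byte ``code >> 3``).
    genome_id : str
        Free-text identifier of the genome the index was built from.
    """

    def __init__(self, k: int, bits: np.ndarray, genome_id: str = "") -> None:
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        expected = (4**k + 7) // 8
        if bits.dtype != np.uint8 or bits.size != expected:
            raise ValueError("bits array does not match 4**k")
        self.k = int(k)
        self._bits = bits
        self.genome_id = genome_id

    # -- construction --------------------------------------------------

    @classmethod
    def from_contigs(
        cls, contigs: Mapping[str, str], k: int, genome_id: str = ""
    ) -> "NullomerIndex":
        """Build the index from a mapping of contig name -> sequence.

        Every k-mer window of each contig and of its reverse complement
        that contains no ambiguous base sets one bit; windows with any
        non-ACGT character are skipped, and contigs shorter than k
        contribute nothing.
        """
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        if not contigs or all(len(s) == 0 for s in contigs.values()):
            raise ValueError("empty genome")
        bits = np.zeros((4**k + 7) // 8, dtype=np.uint8)
        for seq in contigs.values():
            seq = seq.upper()
            for strand in (seq, reverse_complement_lenient(seq)):
                codes = _window_codes(strand, k)
                if codes.size:
                    np.bitwise_or.at(
                        bits,
                        (codes >> np.uint64(3)).astype(np.int64),
                        (np.uint8(1) << (codes & np.uint64(7)).astype(np.uint8)),
                    )
        return cls(k, bits, genome_id)

    @classmethod
    def from_fasta(cls, path, k: int) -> "NullomerIndex":
        from .io import read_fasta

        contigs = read_fasta(path)
        return cls.from_contigs(contigs, k, genome_id=str(path))

    # -- queries -------------------------------------------------------

    @property
    def n_present(self) -> int:
        return int(_POPCOUNT[self._bits].sum())

    @property
    def nullomer_count(self) -> int:
        return 4**self.k - self.n_present

    def contains(self, seq: str) -> bool:
        """True iff ``seq`` occurs in the genome on either strand."""
        if len(seq) != self.k:
            raise ValueError(f"expected length {self.k}, got {len(seq)}")
        code = encode_kmer(seq)
        return bool((self._bits[code >> 3] >> (code & 7)) & 1)

    __contains__ = contains

    def is_nullomer(self, seq: str) -> bool:
        return not self.contains(seq)

    def nullomers(self, chunk: int = 1 << 16) -> Iterator[str]:
        """Yield every absent k-mer exactly once, in code order."""
        k = self.k
        total = 4**k
        for start_byte in range(0, self._bits.size, chunk):
            block = self._bits[start_byte : start_byte + chunk]
            present = np.unpackbits(block, bitorder="little")
            base = start_byte * 8
            for off in np.flatnonzero(present == 0):
                code = base + int(off)
                if code >= total:
                    break
                yield decode_kmer(code, k)

    # -- serialization -------------------------------------------------

    def save(self, path) -> None:
        """Persist as magic + k + genome_id + n_present + raw bit-array."""
        gid = self.genome_id.encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<BH", self.k, len(gid)))
            fh.write(gid)
            fh.write(struct.pack("<Q", self.n_present))
            fh.write(self._bits.tobytes())

    @classmethod
    def load(cls, path) -> "NullomerIndex":
        with open(path, "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise ValueError(f"{path}: not a nullomer index file")
            k, gid_len = struct.unpack("<BH", fh.read(3))
            genome_id = fh.read(gid_len).decode("utf-8")
            (n_present,) = struct.unpack("<Q", fh.read(8))
            bits = np.frombuffer(fh.read(), dtype=np.uint8).copy()
        idx = cls(k, bits, genome_id)
        if idx.n_present != n_present:
            raise ValueError(f"{path}: corrupt index (popcount mismatch)")
        return idx

    def __repr__(self) -> str:
        return (
            f"NullomerIndex(k={self.k}, n_present={self.n_present}, "
            f"nullomer_count={self.nullomer_count}, genome_id={self.genome_id!r})"
        )


def reverse_complement_lenient(seq: str) -> str:
    """Reverse complement that passes non-ACGT characters through.

    Used during index construction, where ambiguous windows are skipped
    rather than rejected; N maps to N and stays invalid in the LUT.
    """
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def build_presence_index(
    contigs: Mapping[str, str], k: int, genome_id: str = ""
) -> NullomerIndex:
    """Functional alias for :meth:`NullomerIndex.from_contigs`."""
    return NullomerIndex.from_contigs(contigs, k, genome_id=genome_id)
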