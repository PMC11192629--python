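"""Mutational channel classification: SBS96 substitutions and ID83 indels.

SBS96 types a single-base substitution by its pyrimidine-strand change
(C>A, C>G, C>T, T>A, T>C, T>G) and its two flanking reference bases,
giving 6 x 16 = 96 channels.  ID83 types insertions and deletions by
size, the affected base (pyrimidine strand) for 1-bp events, the
homopolymer/tandem-repeat context, and for longer deletions the
microhomology at the breakpoint, giving 83 channels.

Label conventions here print the observed run length / repeat copy
number directly: a 1-bp deletion inside a reference homopolymer of
length 6 or more is "1:Del:T:6", an insertion with no adjacent copy of
the inserted base is "1:Ins:T:0", a deletion whose sequence occurs in
``n`` adjacent reference copies (including the deleted one, capped at
6) is "L:Del:R:n", and similarly "L:Ins:R:n" with reference-only copies
capped at 5.  Microhomology channels "L:Del:M:m" carry the breakpoint
homology length m (1..min(L-1, 5)).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

from .kmers import reverse_complement

PYRIMIDINES = "CT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UnclassifiableVariant(ValueError):
    """Variant cannot be assigned a channel (wrong type, contig edge, N)."""


@dataclass(frozen=True)
class ChannelLabel:
    scheme: str  # "SBS96" or "ID83"
    label: str


def sbs96_labels() -> list[str]:
    """The fixed 96-element SBS label universe, sorted."""
    labels = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five in "ACGT":
                for three in "ACGT":
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return sorted(labels)


def id83_labels() -> list[str]:
    """The fixed 83-element indel label universe."""
    labels = []
    for base in PYRIMIDINES:
        labels += [f"1:Del:{base}:{n}" for n in range(1, 7)]
        labels += [f"1:Ins:{base}:{n}" for n in range(0, 6)]
    for length in (2, 3, 4, 5):
        labels += [f"{length}:Del:R:{n}" for n in range(1, 7)]
        labels += [f"{length}:Ins:R:{n}" for n in range(0, 6)]
    for length, max_m in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels += [f"{length}:Del:M:{m}" for m in range(1, max_m + 1)]
    assert len(labels) == 83
    return labels


def classify_sbs96(contigs: Mapping[str, str], variant) -> ChannelLabel:
    """Pyrimidine-strand trinucleotide label for a SNP, e.g. "A[C>T]G"."""
    if variant.variant_type != "SNP":
        raise UnclassifiableVariant(
            f"SBS96 requires a SNP, got {variant.variant_type}"
        )
    contig = contigs[variant.chrom].upper()
    pos0 = variant.pos - 1
    if pos0 < 1 or pos0 > len(contig) - 2:
        raise UnclassifiableVariant("flank unavailable at contig edge")
    tri = contig[pos0 - 1 : pos0 + 2]
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if tri[1] != ref:
        raise UnclassifiableVariant(
            f"reference mismatch: genome {tri[1]} vs MAF {ref}"
        )
    if any(ch not in "ACGT" for ch in tri) or alt not in "ACGT":
        raise UnclassifiableVariant("ambiguous base in trinucleotide context")
    if ref not in PYRIMIDINES:
        tri = reverse_complement(tri)
        ref = _COMP[ref]
        alt = _COMP[alt]
    return ChannelLabel("SBS96", f"{tri[0]}[{ref}>{alt}]{tri[2]}")


def _run_left(contig: str, start: int, base: str) -> int:
    """Length of the run of ``base`` ending just before index ``start``."""
    n = 0
    i = start - 1
    while i >= 0 and contig[i] == base:
        n += 1
        i -= 1
    return n


def _run_right(contig: str, start: int, base: str) -> int:
    """Length of the run of ``base`` starting at index ``start``."""
    n = 0
    i = start
    while i < len(contig) and contig[i] == base:
        n += 1
        i += 1
    return n


def _copies_right(contig: str, start: int, unit: str) -> int:
    n = 0
    L = len(unit)
    while contig[start + n * L : start + (n + 1) * L] == unit:
        n += 1
    return n


def _copies_left(contig: str, end: int, unit: str) -> int:
    n = 0
    L = len(unit)
    while end - (n + 1) * L >= 0 and contig[end - (n + 1) * L : end - n * L] == unit:
        n += 1
    return n


def _pyrimidine(base: str) -> str:
    return base if base in PYRIMIDINES else _COMP[base]


def classify_id83(contigs: Mapping[str, str], variant) -> ChannelLabel:
    """COSMIC-style 83-channel label for an insertion or deletion."""
    if variant.variant_type not in ("INS", "DEL"):
        raise UnclassifiableVariant(
            f"ID83 requires an indel, got {variant.variant_type}"
        )
    contig = contigs[variant.chrom].upper()
    s, e, _ = variant.edit_span()
    if variant.variant_type == "DEL":
        seq = variant.ref.upper()
        if contig[s:e] != seq:
            raise UnclassifiableVariant("reference mismatch for deletion")
        if len(seq) == 1:
            base = seq
            run = _run_left(contig, s, base) + 1 + _run_right(contig, e, base)
            return ChannelLabel(
                "ID83", f"1:Del:{_pyrimidine(base)}:{min(run, 6)}"
            )
        length = min(len(seq), 5)
        copies = 1 + _copies_left(contig, s, seq) + _copies_right(contig, e, seq)
        if copies >= 2:
            return ChannelLabel("ID83", f"{length}:Del:R:{min(copies, 6)}")
        mh = _microhomology(contig, s, e, seq)
        if mh >= 1:
            return ChannelLabel("ID83", f"{length}:Del:M:{min(mh, 5)}")
        return ChannelLabel("ID83", f"{length}:Del:R:1")
    # insertion between s-1 and s
    seq = variant.alt.upper()
    if len(seq) == 1:
        base = seq
        run = _run_left(contig, s, base) + _run_right(contig, s, base)
        return ChannelLabel("ID83", f"1:Ins:{_pyrimidine(base)}:{min(run, 5)}")
    length = min(len(seq), 5)
    copies = _copies_left(contig, s, seq) + _copies_right(contig, s, seq)
    return ChannelLabel("ID83", f"{length}:Ins:R:{min(copies, 5)}")


def _microhomology(contig: str, s: int, e: int, deleted: str) -> int:
    """Longest partial repeat of the deleted sequence at the breakpoint.

    Prefix of the deleted sequence matched against the sequence following
    the deletion, or its suffix matched against the preceding sequence;
    the longer of the two, always < len(deleted).
    """
    L = len(deleted)
    fwd = 0
    while fwd < L - 1 and e + fwd < len(contig) and contig[e + fwd] == deleted[fwd]:
        fwd += 1
    bwd = 0
    while (
        bwd < L - 1
        and s - 1 - bwd >= 0
        and contig[s - 1 - bwd] == deleted[L - 1 - bwd]
    ):
        bwd += 1
    return max(fwd, bwd)
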