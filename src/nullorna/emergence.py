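"""Nullomer emergence from somatic mutations.

A somatic mutation can create k-mers that are absent from the reference
genome.  For each variant we rebuild the local mutated sequence window
(up to k-1 bp of reference flank on each side of the edited span, with
the reference allele replaced by the alternate) and test every k-mer of
that window against the absence index.  Any k-mer of the window lying
entirely in unedited flank is a reference substring and therefore never
survives the membership filter, so scanning the whole window is exactly
equivalent to scanning only edit-overlapping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

import pandas as pd

from .channels import classify_id83, classify_sbs96, UnclassifiableVariant
from .index import NullomerIndex
from .kmers import AmbiguousBaseError, canonical_form

logger = logging.getLogger(__name__)

SUBSTITUTION_TYPES = {"SNP", "DNP", "TNP", "ONP"}
INDEL_TYPES = {"INS", "DEL"}
VARIANT_TYPES = SUBSTITUTION_TYPES | INDEL_TYPES


class ReferenceMismatchError(ValueError):
    """Reference allele does not match the genome at the stated position."""


@dataclass(frozen=True)
class SomaticVariant:
    """One MAF-style somatic mutation record (1-based inclusive coords).

    ``ref == "-"`` denotes a pure insertion (alt inserted between ``pos``
    and ``pos + 1``, MAF convention); ``alt == "-"`` a pure deletion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    sample_id: str
    cancer_type: str = ""
    gene: str = ""
    alt_count: int | None = None
    total_count: int | None = None

    def __post_init__(self):
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.variant_type == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"invalid SNP alleles {self.ref}>{self.alt}")
        elif self.variant_type == "DEL":
            if self.alt != "-" or len(self.ref) < 1 or self.ref == "-":
                raise ValueError(f"invalid DEL alleles {self.ref}>{self.alt}")
        elif self.variant_type == "INS":
            if self.ref != "-" or len(self.alt) < 1 or self.alt == "-":
                raise ValueError(f"invalid INS alleles {self.ref}>{self.alt}")
        else:  # DNP/TNP/ONP: same-length multi-base substitution
            if len(self.ref) != len(self.alt) or "-" in (self.ref, self.alt):
                raise ValueError(
                    f"{self.variant_type} requires same-length ref/alt"
                )
        if self.alt_count is not None and self.total_count is not None:
            if self.alt_count > self.total_count:
                raise ValueError("alt_count exceeds total_count")

    def edit_span(self) -> tuple[int, int, str]:
        """0-based half-open reference span replaced, and the replacement."""
        pos0 = self.pos - 1
        if self.variant_type == "INS":
            return pos0 + 1, pos0 + 1, self.alt
        if self.variant_type == "DEL":
            return pos0, pos0 + len(self.ref), ""
        return pos0, pos0 + len(self.ref), self.alt


@dataclass
class EmergenceRecord:
    """A variant paired with the canonical nullomers it creates at length k."""

    variant: SomaticVariant
    k: int
    emerged: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_emerged(self) -> int:
        return len(self.emerged)

    @property
    def is_emerging(self) -> bool:
        return self.n_emerged >= 1


def vaf(variant: SomaticVariant) -> float:
    """Variant allele frequency: alt reads / total reads at the site."""
    if variant.alt_count is None or variant.total_count is None:
        raise ValueError("read counts unavailable")
    if variant.total_count == 0:
        raise ValueError("total_count is zero")
    return variant.alt_count / variant.total_count


def mutated_window(
    contigs: Mapping[str, str], variant: SomaticVariant, k: int
) -> str:
    """Local mutated sequence: ref flanks of up to k-1 bp around the edit.

    Flanks are truncated at contig boundaries.  Raises
    :class:`ReferenceMismatchError` if the stated reference allele does
    not match the genome, and :class:`AmbiguousBaseError` if the window
    contains a non-ACGT character.
    """
    if variant.chrom not in contigs:
        raise KeyError(f"contig {variant.chrom!r} not in genome")
    contig = contigs[variant.chrom].upper()
    s, e, replacement = variant.edit_span()
    if e > len(contig):
        raise ValueError(
            f"variant at {variant.chrom}:{variant.pos} beyond contig end"
        )
    if variant.ref != "-" and contig[s:e] != variant.ref.upper():
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"MAF says {variant.ref!r}, genome has {contig[s:e]!r}"
        )
    left = contig[max(0, s - (k - 1)) : s]
    right = contig[e : e + (k - 1)]
    window = left + replacement.upper() + right
    for ch in window:
        if ch not in "ACGT":
            raise AmbiguousBaseError(
                f"ambiguous base in mutated window at {variant.chrom}:{variant.pos}"
            )
    return window


def emerged_nullomers(
    index: NullomerIndex,
    contigs: Mapping[str, str],
    variant: SomaticVariant,
) -> EmergenceRecord:
    """Canonical nullomers created by one variant at the index's k."""
    k = index.k
    window = mutated_window(contigs, variant, k)
    emerged = {
        canonical_form(window[i : i + k])
        for i in range(len(window) - k + 1)
        if index.is_nullomer(window[i : i + k])
    }
    return EmergenceRecord(variant=variant, k=k, emerged=frozenset(emerged))


def channel_label(contigs: Mapping[str, str], variant: SomaticVariant) -> str:
    """SBS96 label for SNPs, ID83 for indels, '.' otherwise."""
    try:
        if variant.variant_type == "SNP":
            return classify_sbs96(contigs, variant).label
        if variant.variant_type in INDEL_TYPES:
            return classify_id83(contigs, variant).label
    except UnclassifiableVariant:
        return "."
    return "."


def batch_emergence(
    variants: Iterable[SomaticVariant],
    contigs: Mapping[str, str],
    index: NullomerIndex,
) -> pd.DataFrame:
    """Emergence table: one row per variant, in input order.

    Per-variant failures (reference mismatch, ambiguous window,
    out-of-contig coordinates) are logged and the variant skipped.
    """
    rows = []
    n_skipped = 0
    for v in variants:
        try:
            rec = emerged_nullomers(index, contigs, v)
        except (ReferenceMismatchError, AmbiguousBaseError, KeyError, ValueError) as exc:
            logger.warning("skipping variant %s:%s: %s", v.chrom, v.pos, exc)
            n_skipped += 1
            continue
        rows.append(
            {
                "sample_id": v.sample_id,
                "cancer_type": v.cancer_type,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "variant_type": v.variant_type,
                "channel": channel_label(contigs, v),
                "vaf": (
                    vaf(v)
                    if v.alt_count is not None
                    and v.total_count not in (None, 0)
                    else float("nan")
                ),
                "k": index.k,
                "n_emerged": rec.n_emerged,
                "emerged": tuple(sorted(rec.emerged)),
            }
        )
    if n_skipped:
        logger.warning("batch_emergence skipped %d variant(s)", n_skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "gene",
            "chrom",
            "pos",
            "variant_type",
            "channel",
            "vaf",
            "k",
            "n_emerged",
            "emerged",
        ],
    )
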