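"""cfRNA read screening and count-matrix preprocessing.

Reads are scanned directly for a fixed panel of nullomers (both
strands, overlapping occurrences counted); the resulting samples x
nullomers count matrix is then filtered and normalized in the fixed
order low-count zeroing -> low-sum column removal -> counts-per-million
scaling before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kmers import reverse_complement

logger = logging.getLogger(__name__)


def _panel_lookup(panel: Sequence[str]) -> tuple[dict[str, int], int]:
    """Map every panel k-mer and its reverse complement to its panel index."""
    if not panel:
        raise ValueError("empty panel")
    k = len(panel[0])
    lookup: dict[str, int] = {}
    for i, seq in enumerate(panel):
        s = seq.upper()
        if len(s) != k:
            raise ValueError("panel sequences must all have the same length")
        if any(ch not in "ACGT" for ch in s):
            raise ValueError(f"panel sequence {seq!r} is not plain ACGT")
        rc = reverse_complement(s)
        for key in {s, rc}:
            if key in lookup and lookup[key] != i:
                raise ValueError(
                    f"panel sequences {panel[lookup[key]]!r} and {seq!r} "
                    "collide under reverse complement"
                )
            lookup[key] = i
    return lookup, k


def scan_reads(reads: Iterable[str], panel: Sequence[str]) -> np.ndarray:
    """Occurrences of each panel nullomer across reads, both strands.

    Counts possibly overlapping matches of the nullomer or its reverse
    complement; a palindromic match is counted once.  Reads shorter
    than k contribute nothing, and windows containing N never match.
    """
    lookup, k = _panel_lookup(panel)
    counts = np.zeros(len(panel), dtype=np.int64)
    n_reads = 0
    for read in reads:
        n_reads += 1
        seq = read.upper()
        for i in range(len(seq) - k + 1):
            hit = lookup.get(seq[i : i + k])
            if hit is not None:
                counts[hit] += 1
    if n_reads == 0:
        logger.warning("scan_reads: empty read set, all counts zero")
    return counts


@dataclass(frozen=True)
class CountMatrix:
    """Samples x nullomers occurrence counts with per-sample class labels.

    ``counts`` is a DataFrame indexed by sample_id with one column per
    canonical panel nullomer; ``labels`` maps each sample to "cancer"
    or "healthy"; ``normalized`` flags counts-per-million values.
    """

    counts: pd.DataFrame
    labels: pd.Series
    normalized: bool = False

    def __post_init__(self):
        if not self.counts.index.equals(self.labels.index):
            raise ValueError("counts and labels indexed by different samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        bad = set(self.labels) - {"cancer", "healthy"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def nullomers(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome vector: cancer = 1, healthy = 0."""
        return (self.labels == "cancer").to_numpy(dtype=int)


def build_count_matrix(
    sample_reads: Mapping[str, Iterable[str]],
    sample_labels: Mapping[str, str],
    panel: Sequence[str],
) -> CountMatrix:
    """Scan each sample's reads against the panel and assemble the matrix."""
    rows = {
        sid: scan_reads(reads, panel) for sid, reads in sample_reads.items()
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(panel))
    labels = pd.Series({sid: sample_labels[sid] for sid in counts.index})
    return CountMatrix(counts=counts, labels=labels.loc[counts.index])


def zero_low_counts(matrix: CountMatrix, threshold: int = 2) -> CountMatrix:
    """Set entries <= threshold to zero (false-positive suppression)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    counts = matrix.counts.where(matrix.counts > threshold, 0)
    return replace(matrix, counts=counts)


def filter_low_sum(matrix: CountMatrix, min_sum: int = 10) -> CountMatrix:
    """Drop nullomer columns whose total count across samples is < min_sum."""
    if matrix.counts.shape[1] == 0:
        raise ValueError("no features remain")
    keep = matrix.counts.sum(axis=0) >= min_sum
    if not keep.any():
        raise ValueError("no features remain after low-sum filtering")
    return replace(matrix, counts=matrix.counts.loc[:, keep])


def cpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Scale each sample's row to sum to one million (CPM).

    All-zero rows are left at zero with a warning.
    """
    values = matrix.counts.to_numpy(dtype=float)
    row_sums = values.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        logger.warning(
            "cpm_normalize: %d all-zero sample row(s) left unscaled",
            int(zero_rows.sum()),
        )
    scale = np.where(zero_rows, 1.0, row_sums)
    cpm = values / scale[:, None] * 1e6
    cpm[zero_rows] = 0.0
    counts = pd.DataFrame(
        cpm, index=matrix.counts.index, columns=matrix.counts.columns
    )
    return replace(matrix, counts=counts, normalized=True)


def preprocess(
    matrix: CountMatrix, zero_threshold: int = 2, min_sum: int = 10
) -> CountMatrix:
    """The fixed pipeline: zero_low_counts -> filter_low_sum -> cpm_normalize."""
    return cpm_normalize(
        filter_low_sum(zero_low_counts(matrix, zero_threshold), min_sum)
    )
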