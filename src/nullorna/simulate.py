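"""Synthetic genomes, somatic-mutation cohorts, and cfRNA read sets.

The generators produce toy-scale inputs with the statistical structure
the analysis assumes: a random genome small enough that its nullomer
space at k = 8-10 is non-trivial; MAF-style cohorts with per-patient
Poisson mutation counts, a configurable substitution/indel mix, an
optional hypermutator, and Beta-distributed variant allele fractions;
and case/control FASTQ-style read sets in which case reads carry
spiked nullomer-containing fragments at a configurable per-read rate.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index import NullomerIndex
from .kmers import reverse_complement

_BASES = np.array(list("ACGT"))


def generate_genome(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Single-contig random genome with i.i.d. bases at the given GC."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a synthetic somatic-mutation cohort.

    Defaults give a 4-type x 12-patient cohort averaging 30 mutations
    per patient, 85% SNVs / 5% insertions / 10% deletions (a typical
    WES somatic call composition), sequencing depth ~ Poisson(80) and
    VAF ~ Beta(2, 6).  ``hypermutator`` multiplies one patient's
    mutation count, mirroring extreme-burden tumors.
    """

    n_cancer_types: int = 4
    patients_per_type: int = 12
    mutation_mean: float = 30.0
    substitution_fraction: float = 0.85
    insertion_fraction: float = 0.05
    deletion_fraction: float = 0.10
    hypermutator: tuple[int, float] | None = None  # (patient index, multiplier)
    depth_mean: float = 80.0
    vaf_beta: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self):
        total = (
            self.substitution_fraction
            + self.insertion_fraction
            + self.deletion_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variant-type fractions must sum to 1")
        if self.n_cancer_types < 1 or self.patients_per_type < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.mutation_mean <= 0:
            raise ValueError("mutation mean must be positive")


def generate_cohort(
    genome: str, spec: CohortSpec, contig: str = "chr1"
) -> pd.DataFrame:
    """MAF-style cohort table with ref alleles read from the genome."""
    if not genome:
        raise ValueError("empty genome")
    genome = genome.upper()
    rng = np.random.default_rng(spec.seed)
    margin = 20  # keep indel spans and SBS flanks inside the contig
    if len(genome) <= 2 * margin + 10:
        raise ValueError("genome too short for cohort simulation")
    rows = []
    patient_idx = 0
    for t in range(spec.n_cancer_types):
        ctype = f"CT{t + 1:02d}"
        for p in range(spec.patients_per_type):
            sample = f"{ctype}-P{p + 1:03d}"
            mean = spec.mutation_mean
            if spec.hypermutator is not None and patient_idx == spec.hypermutator[0]:
                mean *= spec.hypermutator[1]
            n_mut = rng.poisson(mean)
            for _ in range(n_mut):
                rows.append(
                    _random_variant(genome, contig, sample, ctype, rng, spec, margin)
                )
            patient_idx += 1
    columns = [
        "Hugo_Symbol",
        "Chromosome",
        "Start_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
        "Variant_Type",
        "Tumor_Sample_Barcode",
        "cancer_type",
        "t_alt_count",
        "t_depth",
    ]
    return pd.DataFrame(rows, columns=columns)


def _random_variant(genome, contig, sample, ctype, rng, spec, margin):
    kind = rng.choice(
        ["SNP", "INS", "DEL"],
        p=[
            spec.substitution_fraction,
            spec.insertion_fraction,
            spec.deletion_fraction,
        ],
    )
    pos0 = int(rng.integers(margin, len(genome) - margin))
    # a handful of synthetic gene symbols so gene-level stats are exercised
    gene = f"GENE{int(rng.integers(1, 13)):02d}"
    depth = max(int(rng.poisson(spec.depth_mean)), 1)
    vaf = rng.beta(*spec.vaf_beta)
    alt_count = int(rng.binomial(depth, vaf))
    if kind == "SNP":
        ref = genome[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        pos, ref_allele, alt_allele = pos0 + 1, ref, alt
    elif kind == "DEL":
        size = int(rng.integers(1, 4))
        pos, ref_allele, alt_allele = pos0 + 1, genome[pos0 : pos0 + size], "-"
    else:  # INS after pos0 (MAF convention)
        size = int(rng.integers(1, 4))
        ins = "".join(rng.choice(_BASES, size=size))
        pos, ref_allele, alt_allele = pos0 + 1, "-", ins
    return {
        "Hugo_Symbol": gene,
        "Chromosome": contig,
        "Start_Position": pos,
        "Reference_Allele": ref_allele,
        "Tumor_Seq_Allele2": alt_allele,
        "Variant_Type": kind,
        "Tumor_Sample_Barcode": sample,
        "cancer_type": ctype,
        "t_alt_count": alt_count,
        "t_depth": depth,
    }


@dataclass(frozen=True)
class ReadSimSpec:
    """Study-condition parameters for synthetic case/control cfRNA reads.

    Case reads carry one embedded panel nullomer with probability
    ``case_spike_rate`` (default 0.05, ten times the control rate),
    emulating tumor-derived fragments among background transcripts.
    Reads are error-free by default; ``error_rate`` adds uniform
    substitution errors outside embedded spans.

    When ``n_case_specific`` is set, the first ``n_case_specific``
    panel nullomers are tumor-associated: case spikes draw only from
    them, while control background spikes draw from the remaining
    panel.  This emulates the compositional structure of the real
    assay — tumor-derived fragments carry recurrent tumor nullomers,
    whereas healthy background hits other sequences — which is the
    structure the downstream count filters and the relative-abundance
    (CPM) normalization are designed around.  Left at ``None``, both
    groups spike uniformly from the whole panel and differ only in
    rate.

    The default read depth keeps control contamination per panel
    nullomer well below the count-zeroing threshold of the downstream
    filter (expected ~0.25 spurious counts per control per nullomer for
    a 20-nullomer panel), so the filter removes control background the
    way it is meant to, while case counts sit well above it.
    """

    spike_panel: tuple[str, ...]
    n_cases: int = 30
    n_controls: int = 30
    reads_per_sample: int = 1000
    read_length: int = 75
    case_spike_rate: float = 0.05
    control_spike_rate: float = 0.005
    error_rate: float = 0.0
    n_case_specific: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.spike_panel:
            raise ValueError("spike panel is empty")
        k = len(self.spike_panel[0])
        if any(len(s) != k for s in self.spike_panel):
            raise ValueError("panel sequences must share one length")
        if self.read_length < k:
            raise ValueError("read length shorter than panel k")
        for r in (self.case_spike_rate, self.control_spike_rate, self.error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_case_specific is not None and not (
            0 < self.n_case_specific < len(self.spike_panel)
        ):
            raise ValueError(
                "n_case_specific must leave both groups a non-empty subpanel"
            )


def simulate_reads(
    genome: str,
    spec: ReadSimSpec,
    index: NullomerIndex | None = None,
) -> tuple[dict[str, list[str]], dict[str, str], pd.DataFrame]:
    """Per-sample read lists, labels, and the embedded-count truth table.

    Every panel sequence is verified to be absent from the genome
    (against ``index`` when given, else by direct substring search on
    both strands) so that control samples at spike rate 0 are exactly
    nullomer-free.
    """
    genome = genome.upper()
    for s in spec.spike_panel:
        if index is not None:
            if len(s) != index.k:
                raise ValueError("panel length differs from index k")
            absent = index.is_nullomer(s)
        else:
            absent = s not in genome and reverse_complement(s) not in genome
        if not absent:
            raise ValueError(f"panel sequence {s!r} is not a nullomer of the genome")
    rng = np.random.default_rng(spec.seed)
    k = len(spec.spike_panel[0])
    L = spec.read_length
    # panel lookup (both strands) used to veto junction artifacts: a spiked
    # read must contain exactly the one embedded occurrence
    lookup: dict[str, int] = {}
    for pi, s in enumerate(spec.spike_panel):
        lookup[s] = pi
        lookup[reverse_complement(s)] = pi

    def _panel_hits(read: str) -> int:
        return sum(
            1 for i in range(len(read) - k + 1) if read[i : i + k] in lookup
        )
    samples: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    truth_rows = []
    if spec.n_case_specific is None:
        case_pool = control_pool = list(range(len(spec.spike_panel)))
    else:
        case_pool = list(range(spec.n_case_specific))
        control_pool = list(range(spec.n_case_specific, len(spec.spike_panel)))
    groups = [
        ("cancer", spec.n_cases, spec.case_spike_rate, case_pool),
        ("healthy", spec.n_controls, spec.control_spike_rate, control_pool),
    ]
    for label, n_samples, rate, pool in groups:
        for i in range(n_samples):
            sid = f"{label[:3]}-{i + 1:03d}"
            embedded = np.zeros(len(spec.spike_panel), dtype=np.int64)
            reads = []
            for _ in range(spec.reads_per_sample):
                start = int(rng.integers(0, len(genome) - L + 1))
                read = list(genome[start : start + L])
                spiked_span = None
                if rng.random() < rate:
                    pi = pool[int(rng.integers(0, len(pool)))]
                    for _attempt in range(100):
                        off = int(rng.integers(0, L - k + 1))
                        start = int(rng.integers(0, len(genome) - L + 1))
                        read = list(genome[start : start + L])
                        read[off : off + k] = spec.spike_panel[pi]
                        if _panel_hits("".join(read)) == 1:
                            break
                    else:  # pragma: no cover - astronomically unlikely
                        raise RuntimeError("could not embed spike cleanly")
                    embedded[pi] += 1
                    spiked_span = (off, off + k)
                if spec.error_rate > 0:
                    for j in range(L):
                        if spiked_span and spiked_span[0] <= j < spiked_span[1]:
                            continue
                        if rng.random() < spec.error_rate:
                            read[j] = str(
                                rng.choice([b for b in "ACGT" if b != read[j]])
                            )
                reads.append("".join(read))
            samples[sid] = reads
            labels[sid] = label
            for pi, seq in enumerate(spec.spike_panel):
                truth_rows.append(
                    {"sample_id": sid, "nullomer": seq, "embedded": int(embedded[pi])}
                )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "nullomer", "embedded"])
    return samples, labels, truth


def pick_nullomer_panel(
    index: NullomerIndex, n: int, seed: int = 0
) -> list[str]:
    """A deterministic random sample of n canonical nullomers of the index.

    Rejects pairs that collide under reverse complement so the panel is
    usable for read scanning.
    """
    from .kmers import canonical_form

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    seen: set[str] = set()
    total = 4**index.k
    if index.nullomer_count < n:
        raise ValueError("index has fewer nullomers than requested")
    while len(chosen) < n:
        code = int(rng.integers(0, total))
        from .kmers import decode_kmer

        s = decode_kmer(code, index.k)
        if not index.is_nullomer(s):
            continue
        c = canonical_form(s)
        if c in seen:
            continue
        seen.add(c)
        chosen.append(c)
    return chosen
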