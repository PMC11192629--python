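"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's bit-array/window machinery:
presence is computed as a plain Python substring set over both strands,
and emergence as the set difference between the mutated contig's and the
reference contig's substring sets.
"""

from __future__ import annotations

import numpy as np
import pytest

from nullorna import (
    CountMatrix,
    ModelConfig,
    NullomerIndex,
    ReadSimSpec,
    build_count_matrix,
    generate_genome,
    pick_nullomer_panel,
    preprocess,
    simulate_reads,
)

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canon(seq: str) -> str:
    r = rc(seq)
    return seq if seq <= r else r


def brute_force_present(contigs: dict[str, str], k: int) -> set[str]:
    """All k-mer substrings of the genome and its reverse complement."""
    present = set()
    for seq in contigs.values():
        seq = seq.upper()
        strands = [seq]
        if set(seq) <= set("ACGT"):
            strands.append(rc(seq))
        else:
            strands.append(
                "".join({"A": "T", "C": "G", "G": "C", "T": "A"}.get(c, "N") for c in seq)[::-1]
            )
        for s in strands:
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if set(w) <= set("ACGT"):
                    present.add(w)
    return present


def brute_force_emerged(genome: str, mutated: str, k: int) -> set[str]:
    """Canonical k-mers of the fully mutated contig absent from the reference."""
    ref = brute_force_present({"c": genome}, k)
    mut = brute_force_present({"c": mutated}, k)
    return {canon(w) for w in mut - ref}


def apply_variant(genome: str, variant) -> str:
    """Rebuild the whole mutated contig for a variant (oracle side)."""
    s, e, replacement = variant.edit_span()
    return genome[:s] + replacement + genome[e:]


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def spiked_dataset():
    """Seeded case/control cfRNA read set with a strong spiked signal.

    30 cases at 10x the control spike rate, error-free reads, with the
    first half of the panel tumor-associated — the conditions under
    which the classifier should separate the groups almost perfectly.
    Session-scoped because scanning is the slow part.
    """
    genome = generate_genome(4000, gc=0.41, seed=11)
    index = NullomerIndex.from_contigs({"chr1": genome}, k=8, genome_id="sim")
    panel = pick_nullomer_panel(index, 20, seed=11)
    spec = ReadSimSpec(
        spike_panel=tuple(panel),
        n_cases=30,
        n_controls=30,
        reads_per_sample=1000,
        read_length=75,
        case_spike_rate=0.05,
        control_spike_rate=0.005,
        error_rate=0.0,
        n_case_specific=10,
        seed=11,
    )
    samples, labels, truth = simulate_reads(genome, spec, index=index)
    matrix = build_count_matrix(samples, labels, panel)
    return {
        "genome": genome,
        "index": index,
        "panel": panel,
        "spec": spec,
        "matrix": matrix,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def spiked_fit(spiked_dataset):
    """Classifier results on the spiked dataset at reduced repeats."""
    from nullorna import tune_and_cv

    processed = preprocess(spiked_dataset["matrix"])
    config = ModelConfig(n_folds=10, seed=7)
    return processed, tune_and_cv(processed, config, n_repeats=10)
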