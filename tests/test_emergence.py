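"""Variant windows and nullomer emergence, checked against brute force."""

import numpy as np
import pytest

from nullorna import (
    AmbiguousBaseError,
    ReferenceMismatchError,
    SomaticVariant,
    batch_emergence,
    build_presence_index,
    emerged_nullomers,
    mutated_window,
    vaf,
)

from conftest import (
    apply_variant,
    brute_force_emerged,
    random_acgt,
)


def _snp(chrom, pos, ref, alt, sample="p1", **kw):
    return SomaticVariant(chrom, pos, ref, alt, "SNP", sample, **kw)


class TestMutatedWindow:
    def test_snp_window_has_k_minus_1_flanks(self):
        v = _snp("c", 4, "A", "C")
        assert mutated_window({"c": "AAAAAAAA"}, v, 2) == "ACA"

    def test_insertion_window_maf_convention(self):
        v = SomaticVariant("c", 4, "-", "G", "INS", "p1")
        assert mutated_window({"c": "ACACACAC"}, v, 3) == "ACGAC"

    def test_deletion_window_joins_flanks(self):
        v = SomaticVariant("c", 5, "A", "-", "DEL", "p1")
        assert mutated_window({"c": "GGAAAAAGG"}, v, 3) == "AAAA"

    def test_flanks_truncate_at_contig_boundaries(self):
        v = _snp("c", 1, "A", "G")
        assert mutated_window({"c": "AACC"}, v, 3) == "GAC"

    def test_reference_mismatch_rejected(self):
        v = _snp("c", 4, "G", "C")
        with pytest.raises(ReferenceMismatchError):
            mutated_window({"c": "AAAAAAAA"}, v, 2)

    def test_ambiguous_window_rejected(self):
        v = _snp("c", 4, "A", "C")
        with pytest.raises(AmbiguousBaseError):
            mutated_window({"c": "AANAAAAA"}, v, 3)


class TestEmergedNullomers:
    def test_snp_emergence_on_homopolymer_genome(self):
        genome = {"c": "AAAAAAAA"}
        idx = build_presence_index(genome, 2)
        rec = emerged_nullomers(idx, genome, _snp("c", 4, "A", "C"))
        assert rec.emerged == frozenset({"AC", "CA"})
        assert rec.n_emerged == 2 and rec.is_emerging

    def test_insertion_emergence(self):
        genome = {"c": "ACACACAC"}
        idx = build_presence_index(genome, 3)
        v = SomaticVariant("c", 4, "-", "G", "INS", "p1")
        rec = emerged_nullomers(idx, genome, v)
        assert rec.emerged == frozenset({"ACG", "CGA", "GAC"})

    def test_homopolymer_deletion_never_emerges(self):
        genome = {"c": "GGAAAAAGG"}
        idx = build_presence_index(genome, 3)
        v = SomaticVariant("c", 5, "A", "-", "DEL", "p1")
        assert emerged_nullomers(idx, genome, v).n_emerged == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_equivalence(self, seed):
        """Emerged set == new canonical substrings of the mutated contig."""
        rng = np.random.default_rng(100 + seed)
        genome = random_acgt(rng, int(rng.integers(200, 1500)))
        contigs = {"c": genome}
        for k in (4, 6):
            idx = build_presence_index(contigs, k)
            for _ in range(8):
                v = _random_variant(rng, genome)
                rec = emerged_nullomers(idx, contigs, v)
                expected = brute_force_emerged(
                    genome, apply_variant(genome, v), k
                )
                assert rec.emerged == frozenset(expected)

    def test_no_reported_kmer_is_a_reference_substring(self):
        rng = np.random.default_rng(42)
        genome = random_acgt(rng, 600)
        contigs = {"c": genome}
        idx = build_presence_index(contigs, 5)
        for _ in range(20):
            v = _random_variant(rng, genome)
            for nullomer in emerged_nullomers(idx, contigs, v).emerged:
                assert not idx.contains(nullomer)


def _random_variant(rng, genome, sample="p1"):
    kind = rng.choice(["SNP", "INS", "DEL"])
    pos0 = int(rng.integers(10, len(genome) - 10))
    if kind == "SNP":
        ref = genome[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return SomaticVariant("c", pos0 + 1, ref, alt, "SNP", sample)
    if kind == "DEL":
        size = int(rng.integers(1, 4))
        return SomaticVariant(
            "c", pos0 + 1, genome[pos0 : pos0 + size], "-", "DEL", sample
        )
    ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
    return SomaticVariant("c", pos0 + 1, "-", ins, "INS", sample)


def test_homopolymer_deletion_property_randomized():
    """1-bp deletions inside runs of length >= k never create nullomers."""
    rng = np.random.default_rng(7)
    k = 6
    n_checked = 0
    while n_checked < 200:
        run_base = str(rng.choice(list("ACGT")))
        run_len = int(rng.integers(k, k + 6))
        left = random_acgt(rng, 40)
        right = random_acgt(rng, 40)
        genome = left + run_base * run_len + right
        contigs = {"c": genome}
        idx = build_presence_index(contigs, k)
        offset = int(rng.integers(0, run_len))
        pos = len(left) + offset + 1
        v = SomaticVariant("c", pos, run_base, "-", "DEL", "p1")
        assert emerged_nullomers(idx, contigs, v).n_emerged == 0
        n_checked += 1


def test_emergence_monotone_in_k():
    """Fraction of emerging variants is non-decreasing with k."""
    rng = np.random.default_rng(8)
    genome = random_acgt(rng, 3000)
    contigs = {"c": genome}
    variants = [_random_variant(rng, genome, f"p{i % 5}") for i in range(120)]
    fractions = []
    for k in (4, 5, 6, 7, 8):
        idx = build_presence_index(contigs, k)
        table = batch_emergence(variants, contigs, idx)
        fractions.append((table["n_emerged"] >= 1).mean())
    assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestBatchEmergence:
    def test_skips_bad_variants_and_preserves_order(self):
        genome = {"c": "ACGTACGTACGTACGT"}
        idx = build_presence_index(genome, 4)
        variants = [
            _snp("c", 5, "A", "G", sample="s1"),
            _snp("c", 6, "A", "T", sample="s2"),  # ref mismatch: genome has C
            _snp("c", 9, "A", "C", sample="s3"),
        ]
        table = batch_emergence(variants, genome, idx)
        assert list(table["sample_id"]) == ["s1", "s3"]

    def test_empty_input_gives_empty_table(self):
        genome = {"c": "ACGT" * 5}
        idx = build_presence_index(genome, 3)
        table = batch_emergence([], genome, idx)
        assert table.empty and "n_emerged" in table.columns

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        genome = random_acgt(rng, 500)
        contigs = {"c": genome}
        idx = build_presence_index(contigs, 5)
        variants = [_random_variant(rng, genome) for _ in range(30)]
        t1 = batch_emergence(variants, contigs, idx)
        t2 = batch_emergence(variants, contigs, idx)
        assert t1.equals(t2)


class TestVaf:
    @pytest.mark.parametrize(
        "alt,total,expected", [(5, 20, 0.25), (0, 10, 0.0), (10, 10, 1.0)]
    )
    def test_values(self, alt, total, expected):
        v = _snp("c", 2, "A", "C", alt_count=alt, total_count=total)
        assert vaf(v) == expected

    def test_missing_counts_unavailable(self):
        with pytest.raises(ValueError, match="unavailable"):
            vaf(_snp("c", 2, "A", "C"))

    def test_zero_depth_rejected(self):
        v = _snp("c", 2, "A", "C", alt_count=0, total_count=0)
        with pytest.raises(ValueError):
            vaf(v)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            _snp("c", 2, "A", "C", alt_count=11, total_count=10)
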