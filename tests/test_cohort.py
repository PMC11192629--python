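"""Cohort-level aggregation: burden, recurrence, specificity, VAF tests."""

import numpy as np
import pandas as pd
import pytest

from nullorna import cohort as co


def _table(rows):
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


def _row(sample, ctype, emerged, gene="G1", vaf=np.nan):
    return {
        "sample_id": sample,
        "cancer_type": ctype,
        "gene": gene,
        "chrom": "c",
        "pos": 1,
        "variant_type": "SNP",
        "channel": ".",
        "vaf": vaf,
        "k": 3,
        "n_emerged": len(emerged),
        "emerged": tuple(sorted(emerged)),
    }


class TestSummarizePatients:
    def test_distinct_nullomers_are_a_set_union(self):
        table = _table(
            [_row("s1", "LUAD", ("AC", "CA")), _row("s1", "LUAD", ("AC",))]
        )
        out = co.summarize_patients(table)
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec.n_mutations == 2
        assert rec.n_emerging_mutations == 2
        assert rec.n_distinct_nullomers == 2

    def test_zero_variant_sample_reported_when_listed(self):
        out = co.summarize_patients(_table([]), samples=[("s0", "LUAD")])
        assert tuple(out.iloc[0][["n_mutations", "n_emerging_mutations",
                                  "n_distinct_nullomers"]]) == (0, 0, 0)

    def test_disjoint_samples_counted_independently(self):
        table = _table(
            [_row("s1", "LUAD", ("AC",)), _row("s2", "LIHC", ("GT", "TA"))]
        )
        out = co.summarize_patients(table).set_index("sample_id")
        assert out.loc["s1", "n_distinct_nullomers"] == 1
        assert out.loc["s2", "n_distinct_nullomers"] == 2


class TestEmergenceProportion:
    def test_global_fraction(self):
        table = _table(
            [_row("s1", "A", ("AC",))] * 3 + [_row("s1", "A", ())]
        )
        assert co.emergence_proportion(table) == 0.75

    def test_extremes(self):
        all_em = _table([_row("s1", "A", ("AC",))] * 2)
        none_em = _table([_row("s1", "A", ())] * 2)
        assert co.emergence_proportion(all_em) == 1.0
        assert co.emergence_proportion(none_em) == 0.0

    def test_per_group_recomposes_to_global(self):
        table = _table(
            [_row("s1", "A", ("AC",))] * 3
            + [_row("s2", "A", ())]
            + [_row("s3", "B", ("GT",))]
            + [_row("s4", "B", ())] * 3
        )
        per_group = co.emergence_proportion(table, by_cancer_type=True)
        sizes = table.groupby("cancer_type").size()
        weighted = (per_group * sizes).sum() / sizes.sum()
        assert weighted == pytest.approx(co.emergence_proportion(table))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            co.emergence_proportion(_table([]))


class TestCorrelation:
    def test_exact_linear_relationships(self):
        up = pd.DataFrame(
            {"n_mutations": [1, 2, 3], "n_distinct_nullomers": [2, 4, 6]}
        )
        down = pd.DataFrame(
            {"n_mutations": [1, 2, 3], "n_distinct_nullomers": [6, 4, 2]}
        )
        assert co.mutation_nullomer_correlation(up)[0] == pytest.approx(1.0)
        assert co.mutation_nullomer_correlation(down)[0] == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        flat = pd.DataFrame(
            {"n_mutations": [2, 2, 2], "n_distinct_nullomers": [1, 2, 3]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            co.mutation_nullomer_correlation(flat)

    def test_poisson_emergence_gives_strong_correlation(self):
        """Each variant emits ~Poisson(lambda) nullomers: r should be high."""
        rng = np.random.default_rng(12)
        rows = []
        for i in range(40):
            n_mut = int(rng.integers(5, 120))
            for j in range(n_mut):
                n_em = int(rng.poisson(2.0))
                emerged = tuple(f"N{i}_{j}_{t}" for t in range(n_em))
                rows.append(_row(f"s{i}", "A", emerged))
        summaries = co.summarize_patients(_table(rows))
        r, p = co.mutation_nullomer_correlation(summaries)
        assert r > 0.9
        assert p < 1e-4


class TestRecurrence:
    def test_counting_and_ranking(self):
        rows = [
            _row("p1", "LUAD", ("X",)),
            _row("p2", "LUAD", ("X",)),
            _row("p3", "LIHC", ("X", "Y")),
            _row("p3", "LIHC", ("X",)),  # second hit in same patient
        ]
        rec = co.recurrence_table(_table(rows), cohort_size=10)
        top = rec.iloc[0]
        assert top.nullomer == "X"
        assert top.n_patients == 3
        assert top.patient_fraction == pytest.approx(0.3)
        assert top.n_cancer_types == 2
        assert rec.iloc[1].nullomer == "Y" and rec.iloc[1].n_patients == 1

    def test_shuffle_invariance_and_tie_rule(self):
        rng = np.random.default_rng(13)
        rows = [
            _row(f"p{i}", "A", (n,))
            for i, n in enumerate(["B", "A", "C", "A", "B", "C"])
        ]
        t1 = co.recurrence_table(_table(rows))
        shuffled = _table([rows[i] for i in rng.permutation(len(rows))])
        t2 = co.recurrence_table(shuffled)
        pd.testing.assert_frame_equal(t1, t2)
        # equal patient counts -> lexicographic order
        assert list(t1["nullomer"]) == ["A", "B", "C"]

    def test_empty_table(self):
        assert co.recurrence_table(_table([])).empty

    def test_top_panel(self):
        rec = co.recurrence_table(
            _table([_row(f"p{i}", "A", (f"N{i}",)) for i in range(5)])
        )
        assert len(co.top_panel(rec, 3)) == 3
        assert co.top_panel(rec, 99) == list(rec["nullomer"])
        with pytest.raises(ValueError):
            co.top_panel(rec, 0)


class TestCancerTypeSpecific:
    def test_definition(self):
        rows = [
            _row("p1", "LUAD", ("X",)),
            _row("p2", "LIHC", ("Y",)),
            _row("p3", "LUAD", ("Y",)),  # Y seen in two types
            _row("p4", "LUAD", ("Z",)),
            _row("p5", "LUAD", ("Z",)),  # Z in two LUAD patients only
        ]
        out = co.cancer_type_specific(_table(rows))
        assert out["LUAD"] == ["X", "Z"]
        assert out["LIHC"] == []

    def test_each_specific_nullomer_in_exactly_one_set(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(60):
            ct = f"T{int(rng.integers(0, 4))}"
            rows.append(_row(f"p{i}", ct, (f"N{int(rng.integers(0, 30))}",)))
        out = co.cancer_type_specific(_table(rows))
        all_specific = [n for nulls in out.values() for n in nulls]
        assert len(all_specific) == len(set(all_specific))
        table = _table(rows)
        total_distinct = len(
            {n for t in table["emerged"] for n in t}
        )
        assert len(all_specific) <= total_distinct

    def test_single_type_rejected(self):
        with pytest.raises(ValueError, match="specificity undefined"):
            co.cancer_type_specific(_table([_row("p1", "LUAD", ("X",))]))


class TestGeneDensity:
    def test_density_and_tie_rule(self):
        rows = (
            [_row("p1", "A", ("X",), gene="TP53")] * 5
            + [_row("p2", "A", ("Y",), gene="KRAS")] * 2
            + [_row("p3", "A", ("Z",), gene="ABCD")] * 2
            + [_row("p4", "A", (), gene="EGFR")]
        )
        out = co.gene_density(
            _table(rows), {"TP53": 1000, "KRAS": 400, "ABCD": 400, "EGFR": 100}
        )
        assert out.iloc[0].gene == "ABCD"  # ties with KRAS, alphabetical
        assert out.iloc[1].gene == "KRAS"
        assert out.iloc[2].gene == "TP53"
        assert out.iloc[2].density == pytest.approx(0.005)
        assert "EGFR" not in set(out["gene"])  # no emerging mutations

    def test_missing_gene_excluded_with_warning(self, caplog):
        rows = [_row("p1", "A", ("X",), gene="NOPE")]
        with caplog.at_level("WARNING"):
            out = co.gene_density(_table(rows), {"TP53": 100})
        assert out.empty
        assert "NOPE" in caplog.text


class TestVafByEmergence:
    def test_identical_groups_no_signal(self):
        rows = [
            _row("p1", "A", ("X",), vaf=0.5),
            _row("p2", "A", ("X",), vaf=0.5),
            _row("p3", "A", (), vaf=0.5),
            _row("p4", "A", (), vaf=0.5),
        ]
        out = co.vaf_by_emergence(_table(rows))
        assert out["emerging"]["median"] == out["non_emerging"]["median"]
        assert out["p_value"] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        """Complete separation at n=3 vs 3: exact two-sided p = 2/20."""
        rows = [
            _row("p1", "A", ("X",), vaf=v) for v in (0.9, 0.8, 0.85)
        ] + [_row(f"q{i}", "A", (), vaf=v) for i, v in enumerate((0.1, 0.2, 0.15))]
        out = co.vaf_by_emergence(_table(rows))
        assert out["emerging"]["median"] - out["non_emerging"]["median"] == (
            pytest.approx(0.7)
        )
        assert out["p_value"] == pytest.approx(0.1)

    def test_shifted_groups_detected_with_power(self):
        """+0.2 VAF shift at n=50/50 rejects at alpha=0.05 in >80% of runs."""
        rng = np.random.default_rng(15)
        rejections = 0
        n_sims = 25
        for _ in range(n_sims):
            rows = [
                _row(f"e{i}", "A", ("X",), vaf=min(rng.beta(2, 6) + 0.2, 1.0))
                for i in range(50)
            ] + [
                _row(f"n{i}", "A", (), vaf=rng.beta(2, 6)) for i in range(50)
            ]
            if co.vaf_by_emergence(_table(rows))["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_sims > 0.8

    def test_one_empty_group_gives_summaries_only(self):
        rows = [_row("p1", "A", ("X",), vaf=0.4), _row("p2", "A", ("Y",), vaf=0.5)]
        out = co.vaf_by_emergence(_table(rows))
        assert out["non_emerging"]["n"] == 0
        assert out["p_value"] is None
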