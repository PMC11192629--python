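"""Cohort-level statistics over an emergence table.

All functions consume the per-variant DataFrame produced by
:func:`nullorna.emergence.batch_emergence` (one row per variant, with an
``emerged`` column of canonical nullomer tuples) and aggregate it into
per-patient burdens, emergence proportions, recurrence rankings,
cancer-type-specific nullomer sets, per-gene mutation densities, and
VAF comparisons between emerging and non-emerging mutations.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def summarize_patients(
    table: pd.DataFrame, samples: Iterable[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-patient mutation and nullomer burden.

    Parameters
    ----------
    table : DataFrame
        Emergence table at a single k.
    samples : optional iterable of (sample_id, cancer_type)
        Samples to report even if they carry zero variants.

    Returns a DataFrame with columns sample_id, cancer_type,
    n_mutations, n_emerging_mutations, n_distinct_nullomers; distinct
    nullomers are counted in canonical k-mer space.
    """
    out: dict[tuple[str, str], list] = {}
    if samples is not None:
        for sid, ct in samples:
            out[(sid, ct)] = [0, 0, set()]
    for row in table.itertuples(index=False):
        key = (row.sample_id, row.cancer_type)
        entry = out.setdefault(key, [0, 0, set()])
        entry[0] += 1
        if row.n_emerged >= 1:
            entry[1] += 1
            entry[2].update(row.emerged)
    rows = [
        {
            "sample_id": sid,
            "cancer_type": ct,
            "n_mutations": n_mut,
            "n_emerging_mutations": n_em,
            "n_distinct_nullomers": len(nulls),
        }
        for (sid, ct), (n_mut, n_em, nulls) in out.items()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "n_mutations",
            "n_emerging_mutations",
            "n_distinct_nullomers",
        ],
    )


def emergence_proportion(
    table: pd.DataFrame, by_cancer_type: bool = False
) -> float | pd.Series:
    """Fraction of variants that create at least one nullomer.

    Globally, or per cancer type when ``by_cancer_type`` is set.
    """
    if table.empty:
        raise ValueError("empty emergence table")
    emerging = table["n_emerged"] >= 1
    if not by_cancer_type:
        return float(emerging.mean())
    return emerging.groupby(table["cancer_type"]).mean()


def mutation_nullomer_correlation(summaries: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) of mutation vs distinct-nullomer counts."""
    x = summaries["n_mutations"].to_numpy(dtype=float)
    y = summaries["n_distinct_nullomers"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 patients")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def recurrence_table(
    table: pd.DataFrame, cohort_size: int | None = None
) -> pd.DataFrame:
    """Per-nullomer recurrence, ranked by distinct-patient count.

    ``cohort_size`` defaults to the number of distinct samples in the
    table; ties in patient count are broken lexicographically by
    nullomer sequence so re-runs and input shuffles give identical
    rankings.
    """
    if cohort_size is None:
        cohort_size = table["sample_id"].nunique() if len(table) else 0
    agg: dict[str, tuple[set, set, set]] = {}
    for row in table.itertuples(index=False):
        for nullomer in row.emerged:
            patients, ctypes, genes = agg.setdefault(
                nullomer, (set(), set(), set())
            )
            patients.add(row.sample_id)
            ctypes.add(row.cancer_type)
            if row.gene:
                genes.add(row.gene)
    rows = [
        {
            "nullomer": nullomer,
            "n_patients": len(patients),
            "patient_fraction": len(patients) / cohort_size,
            "n_cancer_types": len(ctypes),
            "genes": tuple(sorted(genes)),
        }
        for nullomer, (patients, ctypes, genes) in agg.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "nullomer",
            "n_patients",
            "patient_fraction",
            "n_cancer_types",
            "genes",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["n_patients", "nullomer"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def top_panel(recurrence: pd.DataFrame, n: int = 100_000) -> list[str]:
    """First n nullomers of the ranked recurrence table."""
    if n <= 0:
        raise ValueError("panel size must be positive")
    return recurrence["nullomer"].head(n).tolist()


def cancer_type_specific(table: pd.DataFrame) -> dict[str, list[str]]:
    """Nullomers that emerged in exactly one cancer type.

    A nullomer is specific to a cancer type if it emerged in at least
    one patient of that type and in no patient of any other type.
    """
    ctypes = set(table["cancer_type"])
    if len(ctypes) < 2:
        raise ValueError("specificity undefined with fewer than 2 cancer types")
    seen_in: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        for nullomer in row.emerged:
            seen_in.setdefault(nullomer, set()).add(row.cancer_type)
    out: dict[str, list[str]] = {ct: [] for ct in sorted(ctypes)}
    for nullomer, where in seen_in.items():
        if len(where) == 1:
            out[next(iter(where))].append(nullomer)
    return {ct: sorted(nulls) for ct, nulls in out.items()}


def gene_density(
    table: pd.DataFrame, coding_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Genes ranked by density of nullomer-emerging mutations per coding bp."""
    emerging = table[table["n_emerged"] >= 1]
    counts = emerging.groupby("gene").size()
    rows = []
    for gene, n in counts.items():
        if not gene:
            continue
        if gene not in coding_lengths:
            logger.warning("gene %s missing from coding-length map; excluded", gene)
            continue
        length = coding_lengths[gene]
        if length <= 0:
            raise ValueError(f"non-positive coding length for {gene}")
        rows.append({"gene": gene, "n_emerging": int(n), "density": n / length})
    df = pd.DataFrame(rows, columns=["gene", "n_emerging", "density"])
    if len(df):
        df = df.sort_values(
            ["density", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def vaf_by_emergence(
    table: pd.DataFrame, gene: str | None = None
) -> dict:
    """VAF summaries for emerging vs non-emerging mutations + rank test.

    Returns per-group n/mean/median and a two-sided Mann-Whitney U
    p-value; p is None when either group has no available VAFs.
    """
    df = table if gene is None else table[table["gene"] == gene]
    df = df.dropna(subset=["vaf"])
    em = df.loc[df["n_emerged"] >= 1, "vaf"].to_numpy()
    non = df.loc[df["n_emerged"] == 0, "vaf"].to_numpy()

    def _summary(v):
        if len(v) == 0:
            return {"n": 0, "mean": None, "median": None}
        return {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
        }

    result = {"emerging": _summary(em), "non_emerging": _summary(non)}
    if len(em) and len(non):
        u, p = stats.mannwhitneyu(em, non, alternative="two-sided")
        result["u_statistic"] = float(u)
        result["p_value"] = float(p)
    else:
        result["u_statistic"] = None
        result["p_value"] = None
    return result
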