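"""Readers and writers for the formats the pipeline consumes and emits.

FASTA and FASTQ go through Biopython; MAF-style somatic-variant tables
and all report tables are tab-separated UTF-8 with '.' for missing
values and floats at 6 significant digits, so re-runs diff cleanly.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from pathlib import Path
from collections.abc import Iterator

import pandas as pd
from Bio import SeqIO

from .emergence import SomaticVariant

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Ordered contig name -> sequence; name is the first header token."""
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise ValueError(f"{path}: not FASTA (missing '>' header)")
        fh.seek(0)
        for record in SeqIO.parse(fh, "fasta"):
            contigs[record.id] = str(record.seq)
    if not contigs:
        raise ValueError(f"{path}: empty FASTA")
    return contigs


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality) triples; truncated records raise."""
    with _open_text(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(
                    f"{path}: truncated FASTQ record at index {record_index}"
                )
            header, seq, plus, qual = (
                header.rstrip("\n"),
                seq.rstrip("\n"),
                plus.rstrip("\n"),
                qual.rstrip("\n"),
            )
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(
                    f"{path}: malformed FASTQ record at index {record_index}"
                )
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: sequence/quality length mismatch at record "
                    f"{record_index}"
                )
            yield header[1:].split()[0], seq, qual
            record_index += 1


def write_fastq(reads: dict[str, list[str]] | list[str], path) -> None:
    """Write reads (constant quality) as plain or gzip FASTQ."""
    if isinstance(reads, dict):
        items = [(rid, seq) for rid, seq in reads.items()]
    else:
        items = [(f"read{i}", seq) for i, seq in enumerate(reads)]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in items:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_maf(path) -> tuple[list[SomaticVariant], int]:
    """Parse a MAF-style TSV into validated variants.

    Rows that violate the variant invariants are skipped and counted;
    the skip count is returned alongside the variants.  A missing
    required column raises, naming the column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required MAF column {col!r}")
    variants: list[SomaticVariant] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            variants.append(
                SomaticVariant(
                    chrom=d["Chromosome"],
                    pos=int(d["Start_Position"]),
                    ref=d["Reference_Allele"],
                    alt=d["Tumor_Seq_Allele2"],
                    variant_type=d["Variant_Type"],
                    sample_id=d["Tumor_Sample_Barcode"],
                    cancer_type=d.get("cancer_type") or "",
                    gene=d.get("Hugo_Symbol") or "",
                    alt_count=_opt_int(d.get("t_alt_count")),
                    total_count=_opt_int(d.get("t_depth")),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s: skipping MAF row: %s", path, exc)
            n_skipped += 1
    return variants, n_skipped


def _opt_int(value):
    if value is None or value != value or value in (".", ""):
        return None
    return int(float(value))


def write_maf(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#version synthetic\n")
        df.to_csv(fh, sep="\t", index=False)


def read_panel(path) -> list[str]:
    """One nullomer sequence per line; blank lines ignored."""
    with _open_text(path) as fh:
        panel = [line.strip().upper() for line in fh if line.strip()]
    if not panel:
        raise ValueError(f"{path}: empty panel")
    return panel


def write_panel(panel: list[str], path) -> None:
    with open(path, "w") as fh:
        for seq in panel:
            fh.write(seq + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: '.' for missing, floats at 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (tuple, list, set, frozenset))).any():
            out[col] = out[col].map(
                lambda v: ",".join(sorted(v)) if isinstance(v, (tuple, list, set, frozenset)) else v
            )
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_emergence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    df["emerged"] = df["emerged"].map(
        lambda v: tuple(sorted(str(v).split(","))) if isinstance(v, str) and v else ()
    )
    df["gene"] = df["gene"].fillna("")
    df["cancer_type"] = df["cancer_type"].fillna("")
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(tables: dict, metrics: dict, out_dir, config: dict | None = None,
                 inputs: list | None = None) -> Path:
    """Write TSV tables + metrics JSON + a run manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_table(df, out / f"{name}.tsv")
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=str)
    manifest = {
        "package": "nullorna",
        "version": _version(),
        "config": config or {},
        "inputs": {
            str(p): file_sha256(p) for p in (inputs or []) if Path(p).exists()
        },
        "tables": sorted(tables),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("nullorna")
    except Exception:
        return "unknown"
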