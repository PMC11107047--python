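"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; sample sheets and tabular outputs are
TSV via pandas. GFF3 is written 1-based inclusive per the standard while
all in-memory coordinates stay 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

CONDITIONS = ("tumor", "normal")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(path, records) -> None:
    """Write ``records`` (mapping name -> sequence, or iterable of pairs)."""
    items = records.items() if hasattr(records, "items") else records
    with _open_text(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path, reads, quality_char: str = "I") -> None:
    """Write single-end reads (iterable of (name, sequence)) with constant quality."""
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq_sequences(path):
    """Yield upper-cased read sequences from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_gff3(path, genes, chrom_lengths: dict) -> None:
    """Write gene/mRNA/exon features.

    ``genes``: iterable of (gene_id, chrom, strand, exons) with exons a list of
    0-based half-open intervals; converted to 1-based inclusive on output.
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene_id, chrom, strand, exons in genes:
            start = min(s for s, _ in exons) + 1
            end = max(e for _, e in exons)
            fh.write(
                f"{chrom}\tkmerdiff\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            tid = f"{gene_id}.t1"
            fh.write(
                f"{chrom}\tkmerdiff\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={gene_id}\n"
            )
            for i, (s, e) in enumerate(exons, start=1):
                fh.write(
                    f"{chrom}\tkmerdiff\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


def read_gff3(path):
    """Read genes back as (gene_id, chrom, strand, exons 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        for t in db.children(g, featuretype="mRNA"):
            for ex in db.children(t, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))
        genes.append((g.id, g.seqid, g.strand, sorted(exons)))
    return genes


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def load_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    validate_sample_sheet(sheet)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame, require_both_conditions: bool = False):
    if "sample_id" not in sheet.columns or "condition" not in sheet.columns:
        raise ValueError("sample sheet needs 'sample_id' and 'condition' columns")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {bad}; expected one of {CONDITIONS}")
    if require_both_conditions and set(sheet["condition"]) != set(CONDITIONS):
        raise ValueError("both tumor and normal samples are required")
    return sheet
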