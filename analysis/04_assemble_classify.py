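#!/usr/bin/env python
"""Assemble significant k-mers into unitig contigs and classify each into a
transcriptome-event category.

Writes the contig FASTA, the contig table (counts + representative
statistics) and the events table, and reports the per-class counts next to
the planted ground truth.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from kmerdiff import annotate as ann
from kmerdiff import assembly as asm
from kmerdiff import io as kio
from kmerdiff import kmers as km

K = 31

_spec = importlib.util.spec_from_file_location(
    "count_stage", Path(__file__).parent / "02_count_filter_mask.py"
)
_count_stage = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_count_stage)
load_reference = _count_stage.load_reference


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    sheet = kio.load_sample_sheet(args.indir / "samples.tsv")
    conditions = pd.Series(sheet["condition"].values, index=sheet["sample_id"].values)
    masked = km.KmerCountMatrix.from_tsv(args.indir / "counts_masked.tsv", K, sheet)
    normalized = km.KmerCountMatrix.from_tsv(
        args.indir / "counts_normalized.tsv", K, sheet
    )
    de = pd.read_csv(args.indir / "de_kmers.tsv", sep="\t", index_col="kmer")
    sig = pd.read_csv(args.indir / "sig_kmers.tsv", sep="\t", index_col="kmer")
    ref = load_reference(args.indir)

    contigs = asm.assemble(sig.index.tolist())
    for c in contigs:
        asm.quantify_contig(c, normalized, de, M_raw=masked)
    events = ann.annotate_contigs(contigs, ref, conditions)

    fasta, table = asm.contigs_to_tables(contigs)
    kio.write_fasta(args.indir / "contigs.fa", fasta)
    table.to_csv(args.indir / "contigs.tsv", sep="\t", index=False)
    pd.DataFrame({c.contig_id: c.raw_counts for c in contigs}).T.to_csv(
        args.indir / "contig_raw_counts.tsv", sep="\t", index_label="contig_id"
    )
    events.to_csv(args.indir / "events.tsv", sep="\t", index=False)
    ann.blocks_to_bed(events).to_csv(
        args.indir / "events.bed", sep="\t", index=False, header=False
    )

    print(f"{len(sig)} significant k-mers -> {len(contigs)} contigs "
          f"(lengths {min(len(c.sequence) for c in contigs)}-"
          f"{max(len(c.sequence) for c in contigs)} bp)")
    print("event classes:",
          events["event_class"].value_counts().to_dict())
    truth = pd.read_csv(args.indir / "truth.tsv", sep="\t")
    print("planted classes:", truth["event_class"].value_counts().to_dict())


if __name__ == "__main__":
    main()
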