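#!/usr/bin/env python
"""Count canonical 31-mers per sample, apply the recurrence filter and mask
the annotated transcriptome.

Reads the cohort written by 01_simulate_cohort.py; writes the filtered and
masked count matrices as TSV. The recurrence filter keeps k-mers with at
least 5 counts in at least 10 samples; masking removes every k-mer present
in an annotated (spliced) transcript, leaving only variant-derived signal.
"""

import argparse
from pathlib import Path

from kmerdiff import io as kio
from kmerdiff import kmers as km
from kmerdiff import simulate as sim

K = 31


def load_reference(indir: Path) -> sim.Reference:
    chroms = kio.read_fasta(indir / "reference.fa")
    genes = [
        sim.Gene(gene_id=g, chrom=c, strand=s, exons=e)
        for g, c, s, e in kio.read_gff3(indir / "annotation.gff3")
    ]
    transcripts = {
        f"{g.gene_id}.t1": (
            g.gene_id,
            sim.spliced_sequence(chroms[g.chrom], g.exons, g.strand),
        )
        for g in genes
    }
    return sim.Reference(chromosomes=chroms, genes=genes, transcripts=transcripts)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--min-count", type=int, default=5)
    ap.add_argument("--min-samples", type=int, default=10)
    args = ap.parse_args()

    sheet = kio.load_sample_sheet(args.indir / "samples.tsv")
    per_sample = {
        row["sample_id"]: km.count_kmers(args.indir / row["fastq"], K)
        for _, row in sheet.iterrows()
    }
    matrix = km.build_matrix(per_sample, sheet, k=K)
    filtered = km.filter_recurrence(matrix, args.min_count, args.min_samples)
    ref = load_reference(args.indir)
    index = km.index_reference_kmers(ref.transcript_sequences(), K)
    masked = km.mask_reference(filtered, index)

    filtered.to_tsv(args.indir / "counts_filtered.tsv")
    masked.to_tsv(args.indir / "counts_masked.tsv")
    print(f"{len(matrix)} distinct k-mers -> {len(filtered)} after the "
          f"({args.min_count}, {args.min_samples}) recurrence filter")
    print(f"{len(index)} transcriptome k-mers masked -> {len(masked)} "
          f"non-reference k-mers remain")


if __name__ == "__main__":
    main()
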