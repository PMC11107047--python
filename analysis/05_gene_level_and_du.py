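#!/usr/bin/env python
"""Gene-level TPM quantification, gene differential expression, and
differential-usage pairing of significant contigs with their host genes.

A contig is codirectional with its host when both are significant in the
same direction, and a DU pair otherwise — the contrast the reference-free
protocol adds over a conventional gene-level analysis.
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from kmerdiff import downstream as ds
from kmerdiff import io as kio

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
    ref = load_reference(args.indir)
    reads = {
        row["sample_id"]: list(kio.read_fastq_sequences(args.indir / row["fastq"]))
        for _, row in sheet.iterrows()
    }
    gene_tpm, _ = ds.quantify_genes(reads, ref)
    gene_tpm = gene_tpm[list(sheet["sample_id"])]
    gene_de = ds.test_genes(gene_tpm, conditions)

    events = pd.read_csv(args.indir / "events.tsv", sep="\t").fillna({"host_gene": ""})
    contig_table = pd.read_csv(args.indir / "contigs.tsv", sep="\t")
    contig_counts = contig_table.set_index("contig_id")[list(sheet["sample_id"])]
    du = ds.du_pairs(events, gene_de, contig_counts, gene_tpm, conditions)

    gene_tpm.to_csv(args.indir / "gene_tpm.tsv", sep="\t", index_label="gene")
    gene_de.to_csv(args.indir / "de_genes.tsv", sep="\t", index_label="gene")
    du.to_csv(args.indir / "du_pairs.tsv", sep="\t", index=False)

    n_sig = int(gene_de["significant"].sum())
    print(f"{n_sig} / {len(gene_de)} genes significant at the gene level")
    print("contig-host relations:", du["relation"].value_counts().to_dict())
    if not du.empty:
        top = du.iloc[0]
        print(f"top pair: {top['contig_id']} vs {top['host_gene']} "
              f"({top['relation']}, Wilcoxon p={top['wilcoxon_p']:.3g})")


if __name__ == "__main__":
    main()
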