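#!/usr/bin/env python
"""Normalize the masked k-mer matrix and test each k-mer for tumor/normal
differential abundance.

Size factors are median-of-ratios against the geometric-mean
pseudo-reference, estimated on the full filtered matrix (dominated by
non-differential transcriptome k-mers) and applied to the masked one. The
moderated t on log2(x + 0.5) with BH correction selects k-mers at
padj < 0.05 and |log2FC| > 1.
"""

import argparse
from pathlib import Path

from kmerdiff import diffexpr as dx
from kmerdiff import io as kio
from kmerdiff import kmers as km

K = 31


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--lfc", type=float, default=1.0)
    ap.add_argument("--test", choices=["moderated", "welch"], default="moderated")
    args = ap.parse_args()

    sheet = kio.load_sample_sheet(args.indir / "samples.tsv")
    filtered = km.KmerCountMatrix.from_tsv(args.indir / "counts_filtered.tsv", K, sheet)
    masked = km.KmerCountMatrix.from_tsv(args.indir / "counts_masked.tsv", K, sheet)

    sf = dx.size_factors(filtered)
    normalized = dx.normalize(masked, sf)
    de = dx.differential_test(normalized, method=args.test)
    de["padj"] = dx.adjust_pvalues(de["pvalue"].to_numpy())
    sig = dx.select_significant(de, alpha=args.alpha, min_abs_log2fc=args.lfc)

    normalized.to_tsv(args.indir / "counts_normalized.tsv")
    de.to_csv(args.indir / "de_kmers.tsv", sep="\t", index_label="kmer")
    sig.to_csv(args.indir / "sig_kmers.tsv", sep="\t", index_label="kmer")
    up, down = (sig["direction"] == "up").sum(), (sig["direction"] == "down").sum()
    print(f"size factors: tumor median {sf[:10].median():.3f}, "
          f"normal median {sf[10:].median():.3f}")
    print(f"{len(sig)} / {len(de)} masked k-mers significant "
          f"(padj<{args.alpha}, |log2FC|>{args.lfc}): {up} up, {down} down")


if __name__ == "__main__":
    main()
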