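"""End-to-end reference-free differential k-mer pipeline.

Stage order: per-sample canonical k-mer counting -> count matrix ->
recurrence filter -> size-factor estimation (on the filtered, pre-mask
matrix, which is dominated by non-differential annotated-transcript
k-mers) -> reference masking against the annotated transcriptome ->
normalization -> per-k-mer differential test -> unitig assembly of the
significant k-mers -> contig quantification -> alignment-based event
classification -> gene-level TPM/DE -> differential-usage pairing ->
neoantigen screening with peptide extraction.

Masking removes every k-mer of the annotated (spliced) transcripts rather
than of the genome: error-free reads of an unperturbed transcriptome then
leave an empty matrix, while intronic, intergenic and junction-novel
k-mers — the signal the method is after — survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import annotate, assembly, diffexpr, downstream, kmers, simulate


@dataclass
class PipelineConfig:
    """Tunable parameters; defaults are the study conditions emulated by the
    synthetic cohort (k = 31, 75 bp reads, 10 vs 10 samples, 20k reads per
    sample, recurrence thresholds 5 counts / 10 samples, padj < 0.05 and
    |log2FC| > 1)."""

    k: int = 31
    read_length: int = 75
    n_reads: int = 20000
    n_tumor: int = 10
    n_normal: int = 10
    error_rate: float = 0.0
    min_count: int = 5
    min_samples: int = 10
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    test: str = "moderated"
    adjust: str = "bh"
    use_adjusted: bool = True
    pseudocount: float = 0.5
    min_tumor_frac: float = 0.5
    seed_length: int = 15
    max_mismatch_frac: float = 0.05
    min_intron: int = 20
    max_intron: int = 100000
    du_mode: str = "paired"
    mhc_command: str | None = None


@dataclass
class PipelineResult:
    cohort: simulate.Cohort
    filtered: kmers.KmerCountMatrix
    masked: kmers.KmerCountMatrix
    normalized: kmers.KmerCountMatrix
    de_table: pd.DataFrame
    significant: pd.DataFrame
    contigs: list
    events: pd.DataFrame
    gene_tpm: pd.DataFrame
    gene_de: pd.DataFrame
    du: pd.DataFrame
    neo_candidates: pd.DataFrame
    peptides: pd.DataFrame
    peptides_scored: bool

    @property
    def conditions(self) -> pd.Series:
        sheet = self.cohort.sheet
        return pd.Series(sheet["condition"].values, index=sheet["sample_id"].values)


def run_pipeline(
    reference: simulate.Reference | None = None,
    specs=None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    cohort: simulate.Cohort | None = None,
) -> PipelineResult:
    """Run the full pipeline on a (simulated) cohort.

    Either pass a prepared ``cohort`` or let the function generate the
    reference / default event set and simulate one from ``seed``.
    """
    cfg = config or PipelineConfig()
    if cohort is None:
        if reference is None:
            reference = simulate.generate_reference(seed=seed)
        if specs is None:
            specs = simulate.default_event_specs(reference)
        cohort = simulate.simulate_cohort(
            reference,
            specs,
            n_tumor=cfg.n_tumor,
            n_normal=cfg.n_normal,
            n_reads=cfg.n_reads,
            read_length=cfg.read_length,
            error_rate=cfg.error_rate,
            seed=seed,
            k=cfg.k,
        )
    reference = cohort.reference
    conditions = pd.Series(
        cohort.sheet["condition"].values, index=cohort.sheet["sample_id"].values
    )

    per_sample = {}
    for sid, reads in cohort.reads.items():
        h, c = kmers.count_kmer_hashes((s for _, s in reads), cfg.k)
        per_sample[sid] = dict(zip(kmers.hashes_to_kmers(h, cfg.k), c.tolist()))
    matrix = kmers.build_matrix(per_sample, cohort.sheet, k=cfg.k)
    filtered = kmers.filter_recurrence(
        matrix, min_count=cfg.min_count, min_samples=cfg.min_samples
    )
    sf = diffexpr.size_factors(filtered)
    tx_index = kmers.index_reference_kmers(reference.transcript_sequences(), cfg.k)
    masked = kmers.mask_reference(filtered, tx_index)
    normalized = diffexpr.normalize(masked, sf) if len(masked) else masked

    if len(masked):
        de = diffexpr.differential_test(
            normalized, method=cfg.test, pseudocount=cfg.pseudocount
        )
        de["padj"] = diffexpr.adjust_pvalues(de["pvalue"].to_numpy(), method=cfg.adjust)
        sig = diffexpr.select_significant(
            de,
            alpha=cfg.alpha,
            min_abs_log2fc=cfg.min_abs_log2fc,
            use_adjusted=cfg.use_adjusted,
        )
    else:
        de = pd.DataFrame(columns=["baseMeanN", "baseMeanT", "log2FC", "pvalue", "padj"])
        sig = pd.DataFrame(columns=list(de.columns) + ["direction"])

    contigs = assembly.assemble(sig.index.tolist())
    for c in contigs:
        assembly.quantify_contig(c, normalized, de, M_raw=masked)

    if contigs:
        events = annotate.annotate_contigs(
            contigs,
            reference,
            conditions,
            seed_length=cfg.seed_length,
            max_mismatch_frac=cfg.max_mismatch_frac,
            min_intron=cfg.min_intron,
            max_intron=cfg.max_intron,
        )
    else:
        events = pd.DataFrame(
            columns=[
                "contig_id", "event_class", "neo", "host_gene", "status", "chrom",
                "start", "end", "strand", "n_mismatch", "polya", "tandem_period",
                "log2FC", "pvalue", "padj", "length",
            ]
        )

    reads_by_sample = {sid: [s for _, s in r] for sid, r in cohort.reads.items()}
    gene_tpm, _ = downstream.quantify_genes(reads_by_sample, reference)
    gene_tpm = gene_tpm[list(cohort.sheet["sample_id"])]
    gene_de = downstream.test_genes(
        gene_tpm,
        conditions,
        method=cfg.test,
        pseudocount=cfg.pseudocount,
        alpha=cfg.alpha,
        min_abs_log2fc=cfg.min_abs_log2fc,
        adjust=cfg.adjust,
    )

    contig_norm = pd.DataFrame(
        {c.contig_id: c.counts for c in contigs}
    ).T if contigs else pd.DataFrame(columns=conditions.index)
    contig_raw = pd.DataFrame(
        {c.contig_id: c.raw_counts for c in contigs}
    ).T if contigs else pd.DataFrame(columns=conditions.index)

    if contigs:
        du = downstream.du_pairs(
            events,
            gene_de,
            contig_norm,
            gene_tpm,
            conditions=conditions,
            mode=cfg.du_mode,
        )
    else:
        du = pd.DataFrame(
            columns=["contig_id", "host_gene", "contig_direction", "gene_direction",
                     "relation", "wilcoxon_p"]
        )

    neo = downstream.neoantigen_candidates(
        contig_raw, conditions, min_tumor_frac=cfg.min_tumor_frac
    ) if contigs else pd.DataFrame(
        columns=["contig_id", "tumor_recurrence", "n_tumor_positive"]
    )
    seq_of = {c.contig_id: c.sequence for c in contigs}
    all_peps = set()
    for cid in neo["contig_id"]:
        all_peps |= downstream.extract_peptides(seq_of[cid])
    peptides, scored = downstream.mhc_hook(all_peps, command=cfg.mhc_command)

    return PipelineResult(
        cohort=cohort,
        filtered=filtered,
        masked=masked,
        normalized=normalized,
        de_table=de,
        significant=sig,
        contigs=contigs,
        events=events,
        gene_tpm=gene_tpm,
        gene_de=gene_de,
        du=du,
        neo_candidates=neo,
        peptides=peptides,
        peptides_scored=scored,
    )


def diagnostic_kmers(truth_row, tx_index, k: int) -> np.ndarray:
    """Hashes of the variant k-mers absent from the annotated transcriptome
    — the sequence signature by which contigs are attributed to an event."""
    h = np.unique(kmers.encode_canonical(truth_row["variant_seq"], k))
    return h[~tx_index.contains_hashes(h)]


def evaluate_recovery(result: PipelineResult, k: int | None = None) -> pd.DataFrame:
    """Per planted event: was a significant contig of the expected class
    produced? A contig is attributed to an event when it shares a
    diagnostic (non-reference) k-mer with the planted variant."""
    k = k or result.masked.k
    reference = result.cohort.reference
    tx_index = kmers.index_reference_kmers(reference.transcript_sequences(), k)
    class_of = dict(
        zip(result.events["contig_id"], result.events["event_class"])
    )
    contig_hashes = {
        c.contig_id: set(kmers.kmers_to_hashes(c.kmers, k).tolist())
        for c in result.contigs
    }
    expected_label = {
        "snv": "SNV", "splice": "splice", "intron": "intron",
        "lincrna": "lincRNA", "repeat": "repeat", "polya": "polyA",
        "split": "split", "unmapped": "unmapped",
    }
    rows = []
    for _, ev in result.cohort.truth.iterrows():
        diag = set(diagnostic_kmers(ev, tx_index, k).tolist())
        attributed = [
            cid for cid, hs in contig_hashes.items() if hs & diag
        ]
        classes = sorted({class_of[cid] for cid in attributed})
        want = expected_label[ev["event_class"]]
        rows.append(
            {
                "event_id": ev["event_id"],
                "expected_class": want,
                "n_contigs": len(attributed),
                "classes": ",".join(classes),
                "recovered": len(attributed) > 0,
                "correct": want in classes,
            }
        )
    return pd.DataFrame(rows)
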