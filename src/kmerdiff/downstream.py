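"""Gene-level quantification, differential usage and neoantigen screening.

Gene expression uses an exact-substring read assigner: each read (or its
reverse complement) found in m annotated transcripts contributes 1/m to
each, transcript abundances are converted to TPM (reads per base,
normalized to one million), and gene TPM sums its transcripts. This is
valid for low-error synthetic reads; it is not a general pseudoaligner.

A significant contig with a host gene forms a codirectional pair when the
gene is itself significant in the same direction, and a differential-usage
(DU) pair otherwise. Pair-level discordance is scored with a two-sided
Wilcoxon signed-rank test across samples on within-feature z-scored
per-sample values (contig vector vs. gene vector); a rank-sum alternative
(contig tumor vs. normal) is selectable.

Neoantigen candidates are contigs with zero raw count in every normal
sample and a positive count in at least ceil(min_tumor_frac x n_tumor)
tumor samples; their 8-11-aa peptides come from all six reading frames
(contigs are unstranded), split at stop codons. MHC-I binding is delegated
to an optional external scorer hook.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .kmers import revcomp


def quantify_genes(reads_by_sample: dict, reference):
    """Exact-substring transcript quantification; returns (gene TPM, transcript TPM).

    ``reads_by_sample``: sample_id -> iterable of read sequences (or of
    (read_id, sequence) pairs). Reads matching no transcript are dropped.
    Per-sample transcript TPM sums to 1e6 whenever any read was assigned.
    """
    transcripts = reference.transcripts
    if not transcripts:
        raise ValueError("reference has no transcripts to quantify")
    tids = list(transcripts)
    seqs = {tid: transcripts[tid][1] for tid in tids}
    lens = np.array([len(seqs[t]) for t in tids], dtype=float)
    tx_cols, gene_cols = {}, {}
    for sid, reads in reads_by_sample.items():
        counter = Counter(
            r[1] if isinstance(r, tuple) else r for r in reads
        )
        n = np.zeros(len(tids))
        for read, mult in counter.items():
            hits = [
                i
                for i, tid in enumerate(tids)
                if read in seqs[tid] or revcomp(read) in seqs[tid]
            ]
            if hits:
                w = mult / len(hits)
                for i in hits:
                    n[i] += w
        rate = n / lens
        total = rate.sum()
        tpm = rate / total * 1e6 if total > 0 else rate
        tx_cols[sid] = pd.Series(tpm, index=tids)
    tx_tpm = pd.DataFrame(tx_cols)
    gene_ids = pd.Series({tid: transcripts[tid][0] for tid in tids})
    gene_tpm = tx_tpm.groupby(gene_ids).sum()
    return gene_tpm, tx_tpm


def test_genes(
    gene_tpm: pd.DataFrame,
    conditions: pd.Series,
    method: str = "moderated",
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Gene-level differential expression on log2(TPM + c), same contrast
    protocol as the k-mer level. Returns the full table with padj and a
    ``significant`` column."""
    from .diffexpr import adjust_pvalues, differential_test

    de = differential_test(
        gene_tpm, conditions=conditions, method=method, pseudocount=pseudocount
    )
    de["padj"] = adjust_pvalues(de["pvalue"].to_numpy(), method=adjust)
    de["significant"] = (de["padj"] < alpha) & (de["log2FC"].abs() > min_abs_log2fc)
    de["direction"] = np.where(
        ~de["significant"], "ns", np.where(de["log2FC"] > 0, "up", "down")
    )
    return de


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def du_pairs(
    contig_table: pd.DataFrame,
    gene_de: pd.DataFrame,
    contig_counts: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    conditions: pd.Series | None = None,
    mode: str = "paired",
) -> pd.DataFrame:
    """Pair significant contigs with their host genes.

    ``contig_table`` needs contig_id, host_gene and log2FC columns (already
    restricted to significant contigs); ``contig_counts`` / ``gene_tpm`` are
    per-sample matrices indexed by contig_id / gene id. Relation is
    'codirectional' when the host gene is significant with the same sign,
    'DU' otherwise; pairs are ranked by the Wilcoxon p-value.
    """
    if mode not in ("paired", "ranksum"):
        raise ValueError(f"unknown DU mode {mode!r}")
    rows = []
    for _, rec in contig_table.iterrows():
        gene = rec["host_gene"]
        if not gene or gene not in gene_de.index:
            continue
        contig_dir = "up" if rec["log2FC"] > 0 else "down"
        g = gene_de.loc[gene]
        gene_dir = g["direction"] if "direction" in g else "ns"
        relation = "codirectional" if gene_dir == contig_dir else "DU"
        cvec = contig_counts.loc[rec["contig_id"]].to_numpy(dtype=float)
        gvec = gene_tpm.loc[gene].reindex(contig_counts.columns).to_numpy(dtype=float)
        if mode == "paired":
            zc, zg = _zscore(cvec), _zscore(gvec)
            diff = zc - zg
            if np.allclose(diff, 0):
                p = 1.0
            else:
                try:
                    p = float(stats.wilcoxon(zc, zg).pvalue)
                except ValueError:
                    p = 1.0
        else:
            cond = conditions.reindex(contig_counts.columns)
            xt = cvec[(cond == "tumor").to_numpy()]
            xn = cvec[(cond == "normal").to_numpy()]
            try:
                p = float(stats.mannwhitneyu(xt, xn, alternative="two-sided").pvalue)
            except ValueError:
                p = 1.0
        rows.append(
            {
                "contig_id": rec["contig_id"],
                "host_gene": gene,
                "contig_direction": contig_dir,
                "gene_direction": gene_dir,
                "relation": relation,
                "wilcoxon_p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "contig_id", "host_gene", "contig_direction", "gene_direction",
            "relation", "wilcoxon_p",
        ],
    )
    return out.sort_values("wilcoxon_p", kind="stable").reset_index(drop=True)


def neoantigen_candidates(
    contig_raw_counts: pd.DataFrame,
    conditions: pd.Series,
    min_tumor_frac: float = 0.5,
) -> pd.DataFrame:
    """Tumor-specific recurrent contigs.

    A contig qualifies when its raw count is 0 in every normal sample and
    positive in at least ceil(min_tumor_frac x n_tumor) tumor samples;
    presence is raw count > 0 (presence/absence, not normalized level).
    """
    conditions = conditions.reindex(contig_raw_counts.columns)
    tumor_cols = conditions[conditions == "tumor"].index
    normal_cols = conditions[conditions == "normal"].index
    if len(tumor_cols) == 0 or len(normal_cols) == 0:
        raise ValueError("both tumor and normal samples are required")
    need = math.ceil(min_tumor_frac * len(tumor_cols))
    t = contig_raw_counts[tumor_cols]
    n = contig_raw_counts[normal_cols]
    n_pos = (t > 0).sum(axis=1)
    ok = (n == 0).all(axis=1) & (n_pos >= need)
    out = pd.DataFrame(
        {
            "contig_id": contig_raw_counts.index[ok],
            "tumor_recurrence": (n_pos[ok] / len(tumor_cols)).to_numpy(),
            "n_tumor_positive": n_pos[ok].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def extract_peptides(sequence: str, min_len: int = 8, max_len: int = 11) -> set:
    """All 8-11-aa peptides from six-frame translation, split at stops."""
    peptides = set()
    for s in (sequence, revcomp(sequence)):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            for stretch in aa.split("*"):
                for l in range(min_len, max_len + 1):
                    for i in range(len(stretch) - l + 1):
                        peptides.add(stretch[i : i + l])
    return peptides


def mhc_hook(peptides, command: str | None = None):
    """Optionally score peptides with an external MHC-I binding predictor.

    The hook command is run with the peptide list file appended (or
    substituted for a ``{input}`` placeholder) and must print
    ``peptide<TAB>score`` lines. On failure the pipeline continues with
    unscored candidates. Returns (DataFrame with peptide [, score], scored
    flag).
    """
    peptides = sorted(peptides)
    df = pd.DataFrame({"peptide": peptides})
    if command is None:
        return df, False
    with tempfile.TemporaryDirectory() as tmp:
        pep_file = Path(tmp) / "peptides.txt"
        pep_file.write_text("".join(p + "\n" for p in peptides))
        cmd = (
            command.replace("{input}", str(pep_file))
            if "{input}" in command
            else f"{command} {pep_file}"
        )
        try:
            res = subprocess.run(
                cmd, shell=True, capture_output=True, text=True, check=True
            )
        except subprocess.CalledProcessError as exc:
            warnings.warn(
                f"MHC scoring hook failed (exit {exc.returncode}); "
                "continuing with unscored candidates",
                stacklevel=2,
            )
            return df, False
    scores = {}
    for line in res.stdout.splitlines():
        parts = line.strip().split("\t")
        if len(parts) >= 2:
            try:
                scores[parts[0]] = float(parts[1])
            except ValueError:
                continue
    df["score"] = df["peptide"].map(scores)
    return df, True
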