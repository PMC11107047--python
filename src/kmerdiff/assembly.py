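"""Unitig assembly of significant canonical k-mers and contig quantification.

Contigs are maximal non-branching paths in the bidirected (k-1)-overlap
graph over the significant k-mer set: each canonical k-mer is a node with
two orientations, an edge joins oriented k-mers overlapping by k-1 bases,
and extension stops at any branch (a node with other than exactly one
successor, or a successor with other than exactly one predecessor).
Palindromic k-mers terminate extension on their ambiguous side; perfect
cycles are emitted as a single linear traversal starting from the
lexicographically smallest member. Every input k-mer ends up in exactly
one contig and the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import canonical, revcomp


@dataclass
class Contig:
    contig_id: str
    sequence: str
    kmers: list  # member canonical k-mers
    representative: str | None = None
    counts: pd.Series | None = None  # normalized, representative k-mer row
    raw_counts: pd.Series | None = None
    log2fc: float | None = None
    pvalue: float | None = None
    padj: float | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _canon(s: str) -> str:
    rc = revcomp(s)
    return s if s <= rc else rc


def _successors(w: str, S: set) -> list:
    suf = w[1:]
    return [suf + b for b in "ACGT" if _canon(suf + b) in S]


def _predecessors(w: str, S: set) -> list:
    pre = w[:-1]
    return [b + pre for b in "ACGT" if _canon(b + pre) in S]


def assemble(kmers) -> list:
    """Assemble canonical k-mers into unitig contigs.

    Input k-mers must share one length and be canonical. Contigs are
    reported in their canonical orientation, sorted lexicographically, with
    ids ``ctg000001``...
    """
    S = set(kmers)
    if not S:
        return []
    ks = {len(x) for x in S}
    if len(ks) != 1:
        raise ValueError(f"mixed k-mer lengths: {sorted(ks)}")
    for x in S:
        if _canon(x) != x:
            raise ValueError(f"k-mer {x} is not canonical")

    visited: set = set()
    raw = []
    for start in sorted(S):
        if start in visited:
            continue
        if start == revcomp(start):
            visited.add(start)
            raw.append((start, [start]))
            continue
        path = _extend(start, S, visited, direction="right")
        left = _extend(start, S, visited, direction="left", exclude=set(map(_canon, path)))
        oriented = left[::-1] + path  # left part comes back reversed
        members = [_canon(w) for w in oriented]
        visited.update(members)
        seq = oriented[0] + "".join(w[-1] for w in oriented[1:])
        raw.append((min(seq, revcomp(seq)), members))

    raw.sort(key=lambda t: t[0])
    return [
        Contig(contig_id=f"ctg{i + 1:06d}", sequence=seq, kmers=members)
        for i, (seq, members) in enumerate(raw)
    ]


def _extend(start: str, S: set, visited: set, direction: str, exclude=None):
    """Walk from ``start`` in one direction; returns the oriented path
    including ``start`` for 'right', excluding it for 'left'."""
    if direction == "right":
        step, back = _successors, _predecessors
        path = [start]
    else:
        step, back = _predecessors, _successors
        path = []
    members = {_canon(start)} | (exclude or set())
    cur = start
    while True:
        nxts = step(cur, S)
        if len(nxts) != 1:
            break
        nxt = nxts[0]
        cn = _canon(nxt)
        if cn in members or cn in visited:
            break  # cycle closure or previously emitted unitig boundary
        if len(back(nxt, S)) != 1:
            break
        path.append(nxt)
        members.add(cn)
        if nxt == revcomp(nxt):
            break  # palindrome: ambiguous far side
        cur = nxt
    return path


def decompose(sequence: str, k: int) -> list:
    """Canonical k-mers of every k-window of a contig, in order."""
    return [canonical(sequence[i : i + k]) for i in range(len(sequence) - k + 1)]


def quantify_contig(
    contig: Contig,
    M_norm,
    stats: pd.DataFrame,
    M_raw=None,
) -> Contig:
    """Attach counts and DE statistics from the representative member k-mer.

    The representative is the member with the smallest p-value (ties broken
    by smallest adjusted p, then lexicographically); the contig inherits its
    normalized counts, raw counts (if a raw matrix is given) and statistics.
    """
    missing = [m for m in contig.kmers if m not in stats.index]
    if missing:
        raise ValueError(f"contig members missing from statistics: {missing[:3]}")
    sub = stats.loc[contig.kmers]
    padj = sub["padj"] if "padj" in sub else pd.Series(1.0, index=sub.index)
    rep = min(zip(sub["pvalue"], padj, sub.index))[2]
    norm_counts = M_norm.counts if hasattr(M_norm, "counts") else M_norm
    if rep not in norm_counts.index:
        raise ValueError(f"representative k-mer {rep} missing from count matrix")
    contig.representative = rep
    contig.counts = norm_counts.loc[rep]
    if M_raw is not None:
        raw_counts = M_raw.counts if hasattr(M_raw, "counts") else M_raw
        contig.raw_counts = raw_counts.loc[rep]
    contig.log2fc = float(sub.loc[rep, "log2FC"]) if "log2FC" in sub else None
    contig.pvalue = float(sub.loc[rep, "pvalue"])
    contig.padj = float(sub.loc[rep, "padj"]) if "padj" in sub else None
    return contig


def contigs_to_tables(contigs) -> tuple:
    """(FASTA records, contig summary table) for a list of quantified contigs."""
    fasta = [(c.contig_id, c.sequence) for c in contigs]
    rows = []
    for c in contigs:
        row = {
            "contig_id": c.contig_id,
            "sequence": c.sequence,
            "n_kmers": len(c.kmers),
            "representative": c.representative,
            "log2FC": c.log2fc,
            "pvalue": c.pvalue,
            "padj": c.padj,
        }
        if c.counts is not None:
            for s, v in c.counts.items():
                row[s] = v
        rows.append(row)
    return fasta, pd.DataFrame(rows)
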