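"""Contig alignment and transcriptome-event classification.

A lightweight exact-seed / ungapped-extension aligner stands in for a
full splice-aware mapper: at toy-genome scale it is deterministic and can
be cross-checked against exhaustive search. Alignment statuses are
unique / multi / spliced / partial_chimeric / unmapped; classification
maps a contig, its alignment, a poly-A/poly-T run check and an exact
tandem-periodicity check onto one of the event classes

    polyA, split, repeat, splice, SNV, intron, lincRNA, unmapped

with a fixed precedence (first match wins), plus a residual "other" class
for unique exonic perfect matches that cross no annotated junction.
Classification is strand-symmetric: contigs are canonicalized before
alignment, and the poly-A detector accepts both a trailing A-run and a
leading T-run. Anti-sense calls are deliberately not made: the libraries
being emulated are unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kmers import revcomp


@dataclass
class Block:
    """One ungapped aligned block. Genomic and query coordinates are 0-based
    half-open; query coordinates always refer to the canonical orientation
    of the contig. ``mism`` holds (query_pos, genomic_pos, query_base)."""

    chrom: str
    gstart: int
    gend: int
    strand: str
    qstart: int
    qend: int
    mism: list = field(default_factory=list)

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart

    def key(self):
        return (self.chrom, self.strand, self.gstart, self.gend, self.qstart, self.qend)

    def trim_right_to(self, new_qend: int) -> "Block":
        d = self.qend - new_qend
        if d <= 0:
            return self
        if self.strand == "+":
            return replace(
                self,
                qend=new_qend,
                gend=self.gend - d,
                mism=[m for m in self.mism if m[0] < new_qend],
            )
        return replace(
            self,
            qend=new_qend,
            gstart=self.gstart + d,
            mism=[m for m in self.mism if m[0] < new_qend],
        )


@dataclass
class AlignmentResult:
    status: str  # unique | multi | spliced | partial_chimeric | unmapped
    blocks: list
    mismatches: list  # (genomic_pos, query_base) across blocks
    n_genome_hits: int = 0


def _find_all(hay: str, needle: str) -> list:
    out, start = [], 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _extend_seed(q, qpos, seed_len, chrom_seq, gpos, budget, max_consec=3):
    """Ungapped extension around an exact seed hit, right then left, with a
    shared mismatch budget; terminal mismatches are trimmed."""
    L, G = len(q), len(chrom_seq)
    mism = []  # (qpos_in_q, gpos)
    used = 0
    qi, gi = qpos + seed_len, gpos + seed_len
    consec = 0
    while qi < L and gi < G:
        if q[qi] != chrom_seq[gi]:
            if used == budget or consec + 1 > max_consec:
                break
            used += 1
            consec += 1
            mism.append((qi, gi))
        else:
            consec = 0
        qi += 1
        gi += 1
    qe, ge = qi, gi
    qj, gj = qpos, gpos
    consec = 0
    while qj > 0 and gj > 0:
        if q[qj - 1] != chrom_seq[gj - 1]:
            if used == budget or consec + 1 > max_consec:
                break
            used += 1
            consec += 1
            mism.append((qj - 1, gj - 1))
        else:
            consec = 0
        qj -= 1
        gj -= 1
    qs, gs = qj, gj
    mism.sort()
    # trim terminal mismatches
    while mism and mism[-1][0] == qe - 1:
        mism.pop()
        qe -= 1
        ge -= 1
    while mism and mism[0][0] == qs:
        mism.pop(0)
        qs += 1
        gs += 1
    return qs, qe, gs, ge, mism


def _gap(b1: Block, b2: Block) -> int:
    """Genomic gap between query-ordered blocks b1 < b2 on one strand."""
    if b1.strand == "+":
        return b2.gstart - b1.gend
    return b1.gstart - b2.gend


def align_contig(
    seq: str,
    reference,
    seed_length: int = 15,
    max_mismatch_frac: float = 0.05,
    min_intron: int = 20,
    max_intron: int = 100000,
) -> AlignmentResult:
    """Align one contig to the reference chromosomes.

    Decision ladder: full-length exact hits on both strands (>=2 loci ->
    multi, 1 -> unique with 0 mismatches); otherwise exact seeds of
    ``seed_length`` are extended without gaps under a floor(frac*len)
    mismatch budget, and the block layout decides unique-with-mismatches,
    spliced (two query-adjacent same-strand blocks with an intron-sized
    genomic gap), partial_chimeric (discordant or partial blocks) or
    unmapped.
    """
    chroms = reference.chromosomes if hasattr(reference, "chromosomes") else reference
    L = len(seq)
    cseq = min(seq, revcomp(seq))
    palindrome = cseq == revcomp(cseq)

    exact = []
    for chrom, cs in chroms.items():
        for strand, q in (("+", cseq), ("-", revcomp(cseq))):
            if palindrome and strand == "-":
                continue
            for pos in _find_all(cs, q):
                exact.append(
                    Block(chrom, pos, pos + L, strand, 0, L)
                )
    if len(exact) >= 1:
        exact.sort(key=lambda b: (b.chrom, b.gstart, b.strand))
        status = "unique" if len(exact) == 1 else "multi"
        return AlignmentResult(
            status=status, blocks=exact[:10], mismatches=[], n_genome_hits=len(exact)
        )

    if L < seed_length:
        warnings.warn(f"contig of length {L} is shorter than the seed length", stacklevel=2)
        return AlignmentResult("unmapped", [], [], 0)

    budget = int(max_mismatch_frac * L)
    qpositions = list(range(0, L - seed_length + 1, seed_length))
    if qpositions[-1] != L - seed_length:
        qpositions.append(L - seed_length)

    blocks, seen = [], set()
    for chrom, cs in chroms.items():
        for strand, q in (("+", cseq), ("-", revcomp(cseq))):
            if palindrome and strand == "-":
                continue
            for qpos in qpositions:
                seed = q[qpos : qpos + seed_length]
                for gpos in _find_all(cs, seed):
                    qs, qe, gs, ge, mm = _extend_seed(
                        q, qpos, seed_length, cs, gpos, budget
                    )
                    if strand == "+":
                        b = Block(
                            chrom, gs, ge, "+", qs, qe,
                            [(qp, gp, q[qp]) for qp, gp in mm],
                        )
                    else:
                        b = Block(
                            chrom, gs, ge, "-", L - qe, L - qs,
                            [(L - 1 - qp, gp, q[qp]) for qp, gp in mm],
                        )
                        b.mism.sort()
                    if b.key() not in seen:
                        seen.add(b.key())
                        blocks.append(b)
    if not blocks:
        return AlignmentResult("unmapped", [], [], 0)
    blocks.sort(key=lambda b: (-b.qlen, len(b.mism), b.chrom, b.gstart, b.strand))

    def mism_of(bs):
        return sorted((g, base) for b in bs for _, g, base in b.mism)

    full = [b for b in blocks if b.qlen >= 0.95 * L - 1e-9 and len(b.mism) <= budget]
    loci = sorted({(b.chrom, b.strand, b.gstart) for b in full})
    if len(loci) >= 2:
        return AlignmentResult("multi", full[:10], mism_of(full[:1]), len(loci))
    if len(loci) == 1:
        best = full[0]
        return AlignmentResult("unique", [best], mism_of([best]), 1)

    max_overlap = 2 * budget + 4
    spliced_best, chim_best = None, None
    for i, b1 in enumerate(blocks):
        for b2 in blocks:
            if b2 is b1 or b2.qstart < b1.qstart:
                continue
            if b2.qstart == b1.qstart and b2.key() <= b1.key():
                continue
            o = b1.qend - b2.qstart
            if o > max_overlap:
                continue
            b1t = b1.trim_right_to(b2.qstart) if o > 0 else b1
            if b1t.qlen <= 0:
                continue
            joint = b1t.qlen + b2.qlen
            adj = 0 <= b2.qstart - b1t.qend <= 2
            same = b1t.chrom == b2.chrom and b1t.strand == b2.strand
            gap = _gap(b1t, b2) if same else None
            cand = (joint, b1t, b2)
            if (
                adj
                and same
                and gap is not None
                and min_intron <= gap <= max_intron
                and joint >= 0.95 * L - 1e-9
            ):
                if spliced_best is None or _pair_key(cand) < _pair_key(spliced_best):
                    spliced_best = cand
            elif joint >= 0.6 * L - 1e-9 and (
                not same or gap is None or gap < min_intron or gap > max_intron
            ):
                if chim_best is None or _pair_key(cand) < _pair_key(chim_best):
                    chim_best = cand
    if spliced_best is not None:
        _, b1, b2 = spliced_best
        return AlignmentResult("spliced", [b1, b2], mism_of([b1, b2]), 0)
    if chim_best is not None:
        _, b1, b2 = chim_best
        return AlignmentResult("partial_chimeric", [b1, b2], mism_of([b1, b2]), 0)
    best = blocks[0]
    if 0.25 * L <= best.qlen < 0.95 * L:
        return AlignmentResult("partial_chimeric", [best], mism_of([best]), 0)
    return AlignmentResult("unmapped", [], [], 0)


def _pair_key(cand):
    joint, b1, b2 = cand
    return (-joint, b1.chrom, b1.gstart, b2.chrom, b2.gstart)


def detect_polya(seq: str, min_run: int = 10):
    """Detect a terminal poly-A tail or leading poly-T head.

    Returns (kind, core) with kind in {'tail_A', 'head_T', 'none'}; the
    core is the contig with the detected run removed. When both runs reach
    ``min_run`` the longer one wins (tie -> tail_A).
    """
    tail = len(seq) - len(seq.rstrip("A"))
    head = len(seq) - len(seq.lstrip("T"))
    if tail >= min_run and tail >= head:
        return "tail_A", seq[: len(seq) - tail]
    if head >= min_run:
        return "head_T", seq[head:]
    return "none", seq


def detect_tandem(seq: str, max_unit: int = 30):
    """Smallest exact period p <= max_unit with >=2 full unit copies.

    The contig must equal the unit repeated, the final copy possibly
    truncated (a prefix of the unit). Returns the period or None.
    """
    n = len(seq)
    for p in range(1, min(max_unit, n // 2) + 1):
        if all(seq[i] == seq[i % p] for i in range(n)):
            return p
    return None


def _gene_span_overlap(block: Block, gene) -> int:
    if gene.chrom != block.chrom:
        return 0
    s, e = gene.span
    return max(0, min(e, block.gend) - max(s, block.gstart))


def _intron_fraction(block: Block, genes) -> float:
    if block.qlen == 0:
        return 0.0
    cover = 0
    for g in genes:
        if g.chrom != block.chrom:
            continue
        for s, e in g.introns:
            cover += max(0, min(e, block.gend) - max(s, block.gstart))
    return min(cover, block.qlen) / block.qlen


def _crosses_exon_boundary(block: Block, genes) -> bool:
    for g in genes:
        if g.chrom != block.chrom:
            continue
        for s, e in g.exons:
            for boundary in (s, e):
                if block.gstart < boundary < block.gend:
                    return True
    return False


def classify(
    aln: AlignmentResult,
    polya_kind: str,
    tandem_period,
    reference,
    min_intron_frac: float = 0.5,
) -> str:
    """Assign one event class by fixed precedence (first match wins).

    ``aln`` must be the alignment of the poly-A-trimmed core whenever a
    run was detected.
    """
    genes = reference.genes if hasattr(reference, "genes") else reference
    if polya_kind != "none" and aln.status == "unmapped":
        return "polyA"
    if aln.status == "partial_chimeric":
        return "split"
    if aln.status == "multi" or tandem_period is not None:
        return "repeat"
    if aln.status == "spliced":
        return "splice"
    if aln.status == "unique":
        block = aln.blocks[0]
        if aln.mismatches:
            return "SNV"
        if _intron_fraction(block, genes) >= min_intron_frac:
            return "intron"
        if not any(_gene_span_overlap(block, g) > 0 for g in genes):
            return "lincRNA"
        if _crosses_exon_boundary(block, genes):
            return "splice"
        return "other"
    return "unmapped"


def assign_host_gene(aln: AlignmentResult, genes):
    """Gene whose span overlaps the most aligned bases; ties break to the
    lexicographically smallest gene id; None when nothing overlaps."""
    if not aln.blocks:
        return None
    best, best_ov = None, 0
    for g in sorted(genes, key=lambda g: g.gene_id):
        ov = sum(_gene_span_overlap(b, g) for b in aln.blocks)
        if ov > best_ov:
            best, best_ov = g.gene_id, ov
    return best


def flag_neo(raw_counts: pd.Series, conditions: pd.Series) -> bool:
    """Tumor-specific flag: zero raw count in every normal sample and a
    positive count in at least one tumor sample."""
    conditions = conditions.reindex(raw_counts.index)
    normal = raw_counts[conditions == "normal"]
    if normal.empty:
        raise ValueError("flag_neo requires at least one normal sample")
    tumor = raw_counts[conditions == "tumor"]
    return bool((normal == 0).all() and (tumor > 0).any())


def annotate_contig(
    seq: str,
    reference,
    seed_length: int = 15,
    max_mismatch_frac: float = 0.05,
    min_intron: int = 20,
    max_intron: int = 100000,
    polya_min_run: int = 10,
    tandem_max_unit: int = 30,
):
    """Full annotation of one contig: poly-A trim, tandem check, alignment
    of the (possibly trimmed) core, classification and host-gene call."""
    polya_kind, core = detect_polya(seq, min_run=polya_min_run)
    period = detect_tandem(seq, max_unit=tandem_max_unit)
    target = core if polya_kind != "none" else seq
    if len(target) >= seed_length:
        aln = align_contig(
            target,
            reference,
            seed_length=seed_length,
            max_mismatch_frac=max_mismatch_frac,
            min_intron=min_intron,
            max_intron=max_intron,
        )
    else:
        aln = AlignmentResult("unmapped", [], [], 0)
    cls = classify(aln, polya_kind, period, reference)
    host = assign_host_gene(aln, reference.genes)
    return aln, cls, host, polya_kind, period


def annotate_contigs(contigs, reference, conditions: pd.Series, **params) -> pd.DataFrame:
    """Annotate a list of quantified contigs into an events table."""
    rows = []
    for c in contigs:
        aln, cls, host, polya_kind, period = annotate_contig(
            c.sequence, reference, **params
        )
        neo = (
            flag_neo(c.raw_counts, conditions) if c.raw_counts is not None else False
        )
        first = aln.blocks[0] if aln.blocks else None
        rows.append(
            {
                "contig_id": c.contig_id,
                "event_class": cls,
                "neo": neo,
                "host_gene": host or "",
                "status": aln.status,
                "chrom": first.chrom if first else "",
                "start": first.gstart if first else -1,
                "end": first.gend if first else -1,
                "strand": first.strand if first else ".",
                "n_mismatch": len(aln.mismatches),
                "polya": polya_kind,
                "tandem_period": period if period is not None else 0,
                "log2FC": c.log2fc,
                "pvalue": c.pvalue,
                "padj": c.padj,
                "length": len(c.sequence),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "event_class", "neo", "host_gene", "status", "chrom",
            "start", "end", "strand", "n_mismatch", "polya", "tandem_period",
            "log2FC", "pvalue", "padj", "length",
        ],
    )


def blocks_to_bed(contigs_events) -> pd.DataFrame:
    """BED-style (0-based half-open) table of primary aligned blocks."""
    df = contigs_events
    bed = df.loc[df["start"] >= 0, ["chrom", "start", "end", "contig_id", "strand"]]
    bed = bed.copy()
    bed.insert(4, "score", 0)
    return bed[["chrom", "start", "end", "contig_id", "score", "strand"]]
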