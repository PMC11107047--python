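"""Synthetic tumor/normal cohort generator with planted transcriptome events.

The generator builds a toy reference (random chromosomes, multi-exon genes
with one transcript each, GFF3-compatible coordinates) and plants
condition-specific variants of eight event classes:

snv        transcript copy differing at exactly one base
splice     exon-skipped transcript (novel junction)
intron     transcript retaining one full intron
lincrna    novel transcript taken from an intergenic interval
repeat     tandem expansion (>=2 exact copies of a short unit) inserted
           into a transcript
polya      novel sequence absent from the genome ending in a poly-A tail
split      fusion-like prefix of one gene's transcript joined to the
           suffix of another's
unmapped   random foreign sequence sharing no k-mer with the reference

Differential events carry a tumor/normal abundance-multiplier pair
(default 4x tumor); tumor-only ("neo") events have zero normal abundance
and may be restricted to a fraction of tumor samples to emulate recurrence.
Reads are single-end, unstranded (random orientation), uniform across each
transcript, with i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as kio
from .kmers import encode_canonical, index_reference_kmers, revcomp

EVENT_CLASSES = (
    "snv",
    "splice",
    "intron",
    "lincrna",
    "repeat",
    "polya",
    "split",
    "unmapped",
)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list  # sorted, non-overlapping 0-based half-open intervals

    @property
    def span(self):
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self):
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Reference:
    chromosomes: dict  # name -> sequence
    genes: list  # of Gene
    transcripts: dict  # transcript_id -> (gene_id, spliced sequence)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    def transcript_of_gene(self, gene_id: str):
        for tid, (gid, seq) in self.transcripts.items():
            if gid == gene_id:
                return tid, seq
        raise KeyError(f"no transcript for gene {gene_id!r}")

    def transcript_sequences(self) -> list:
        return [seq for _, seq in self.transcripts.values()]

    def intergenic_intervals(self, min_len: int = 1000) -> list:
        """(chrom, start, end) intervals not covered by any gene span."""
        out = []
        for chrom, seq in self.chromosomes.items():
            spans = sorted(g.span for g in self.genes if g.chrom == chrom)
            pos = 0
            for s, e in spans:
                if s - pos >= min_len:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
            if len(seq) - pos >= min_len:
                out.append((chrom, pos, len(seq)))
        return out

    def validate(self) -> None:
        for g in self.genes:
            clen = len(self.chromosomes[g.chrom])
            prev_end = -1
            for s, e in g.exons:
                if not (0 <= s < e <= clen):
                    raise ValueError(f"exon {s, e} of {g.gene_id} out of bounds")
                if s <= prev_end:
                    raise ValueError(f"exons of {g.gene_id} overlap or are unsorted")
                prev_end = e
        for tid, (gid, seq) in self.transcripts.items():
            g = self.gene(gid)
            if seq != spliced_sequence(self.chromosomes[g.chrom], g.exons, g.strand):
                raise ValueError(f"transcript {tid} inconsistent with exons")

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kio.write_fasta(outdir / "reference.fa", self.chromosomes)
        kio.write_gff3(
            outdir / "annotation.gff3",
            [(g.gene_id, g.chrom, g.strand, g.exons) for g in self.genes],
            {c: len(s) for c, s in self.chromosomes.items()},
        )


def spliced_sequence(chrom_seq: str, exons, strand: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in exons)
    return revcomp(s) if strand == "-" else s


def _random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_reference(
    n_chromosomes: int = 2,
    chromosome_length: int = 100000,
    n_genes: int = 20,
    exons_per_gene: int = 3,
    seed: int = 0,
    exon_length: int = 300,
    intron_length: int = 400,
    min_gap: int = 1200,
) -> Reference:
    """Deterministically generate a toy genome plus gene annotation.

    Genes are placed without overlap, separated by intergenic gaps of at
    least ``min_gap`` (>= 1 kb by default, so lincRNA events can be planted).
    Raises ValueError when the requested genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": _random_seq(rng, chromosome_length)
        for i in range(n_chromosomes)
    }
    footprint = exons_per_gene * exon_length + max(exons_per_gene - 1, 0) * intron_length
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1
    if any((fp := c * (footprint + min_gap) + min_gap) > chromosome_length for c in per_chrom):
        raise ValueError(
            f"cannot pack {max(per_chrom)} genes of footprint {footprint} plus "
            f"{min_gap} bp gaps into a {chromosome_length} bp chromosome"
        )
    genes = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        # leave head room so gaps can vary while still fitting
        slack = chromosome_length - per_chrom[ci] * (footprint + min_gap) - min_gap
        extra = slack // (per_chrom[ci] + 1) if per_chrom[ci] else 0
        pos = 0
        for _ in range(per_chrom[ci]):
            pos += min_gap + int(rng.integers(0, max(extra, 1)))
            exons = [
                (
                    pos + j * (exon_length + intron_length),
                    pos + j * (exon_length + intron_length) + exon_length,
                )
                for j in range(exons_per_gene)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(gene_id=f"g{gi + 1:03d}", chrom=chrom, strand=strand, exons=exons)
            )
            gi += 1
            pos = exons[-1][1]
    transcripts = {
        f"{g.gene_id}.t1": (
            g.gene_id,
            spliced_sequence(chroms[g.chrom], g.exons, g.strand),
        )
        for g in genes
    }
    ref = Reference(chromosomes=chroms, genes=genes, transcripts=transcripts)
    ref.validate()
    return ref


@dataclass
class EventSpec:
    """One planted transcriptome event.

    Condition abundances are multipliers on ``base_abundance``, the
    variant's expression level relative to one baseline transcript (0.25 by
    default: variants behave as minor isoforms, so the bulk of the k-mer
    table stays non-differential, which median-of-ratios normalization
    relies on). ``tumor_fraction`` is the fraction of tumor samples
    carrying the event (1.0 = fully recurrent); tumor-only events must have
    zero normal abundance.
    """

    event_id: str
    event_class: str
    gene: str | None = None
    gene_b: str | None = None  # second partner, split events only
    tumor_only: bool = False
    tumor_abundance: float = 4.0
    normal_abundance: float = 1.0
    base_abundance: float = 0.25
    tumor_fraction: float = 1.0

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(
                f"unknown event class {self.event_class!r}; one of {EVENT_CLASSES}"
            )
        if self.tumor_only:
            self.normal_abundance = 0.0
        if self.tumor_abundance <= 0 and self.normal_abundance <= 0:
            raise ValueError("event must have positive abundance in some condition")


@dataclass
class PoolEntry:
    name: str
    sequence: str
    abundance: float
    carrier_fraction: float = 1.0


def _exon_segments(gene: Gene):
    """Exon intervals in transcript coordinates, transcript orientation.

    Yields (t_start, t_end, exon_genomic_interval) with exons reversed for
    minus-strand genes.
    """
    exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    segs, pos = [], 0
    for ex in exons:
        length = ex[1] - ex[0]
        segs.append((pos, pos + length, ex))
        pos += length
    return segs


def _safe_exon_position(gene: Gene, transcript_len: int, margin: int) -> int:
    """Transcript coordinate at the middle of the largest exon, at least
    ``margin`` away from the transcript ends and from exon boundaries."""
    segs = sorted(_exon_segments(gene), key=lambda s: (-(s[1] - s[0]), s[0]))
    for s, e, _ in segs:
        pos = (s + e) // 2
        if (
            pos - margin >= max(s, 0)
            and pos + margin <= min(e, transcript_len)
            and pos >= margin
            and pos <= transcript_len - margin
        ):
            return pos
    raise ValueError(f"gene {gene.gene_id}: no exon position with margin {margin}")


def transcript_to_genomic(gene: Gene, tpos: int) -> int:
    for s, e, ex in _exon_segments(gene):
        if s <= tpos < e:
            if gene.strand == "+":
                return ex[0] + (tpos - s)
            return ex[1] - 1 - (tpos - s)
    raise ValueError(f"transcript position {tpos} outside {gene.gene_id}")


def _has_novel_kmer(seq: str, index, k: int) -> bool:
    h = encode_canonical(seq, k)
    return bool((~index.contains_hashes(np.unique(h))).any())


def _all_kmers_novel(seq: str, index, k: int) -> bool:
    h = encode_canonical(seq, k)
    return not bool(index.contains_hashes(np.unique(h)).any())


def plant_events(reference: Reference, specs, seed: int = 0, k: int = 31):
    """Plant the requested events; return (truth table, tumor pool, normal pool).

    Pools contain the baseline annotated transcripts (abundance 1 in both
    conditions) plus one variant sequence per event at its per-condition
    abundance. Every variant is asserted to contain at least one canonical
    k-mer absent from the annotated-transcript k-mer index.
    """
    rng = np.random.default_rng([seed, 7])
    tx_index = index_reference_kmers(reference.transcript_sequences(), k)
    genome_index = index_reference_kmers(reference.chromosomes, k)

    baseline = [
        PoolEntry(name=tid, sequence=seq, abundance=1.0)
        for tid, (_, seq) in reference.transcripts.items()
    ]
    tumor_pool = list(baseline)
    normal_pool = list(baseline)
    rows = []

    for spec in specs:
        seq, locus = _build_variant(reference, spec, rng, k, genome_index, tx_index)
        if not _has_novel_kmer(seq, tx_index, k):
            raise RuntimeError(
                f"event {spec.event_id}: variant contains no non-reference k-mer"
            )
        if spec.tumor_abundance > 0:
            tumor_pool.append(
                PoolEntry(
                    name=spec.event_id,
                    sequence=seq,
                    abundance=spec.tumor_abundance * spec.base_abundance,
                    carrier_fraction=spec.tumor_fraction,
                )
            )
        if spec.normal_abundance > 0:
            normal_pool.append(
                PoolEntry(
                    name=spec.event_id,
                    sequence=seq,
                    abundance=spec.normal_abundance * spec.base_abundance,
                )
            )
        rows.append(
            {
                "event_id": spec.event_id,
                "event_class": spec.event_class,
                "variant_seq": seq,
                "locus": locus,
                "tumor_only": spec.tumor_only,
                "gene": spec.gene or "",
                "tumor_abundance": spec.tumor_abundance,
                "normal_abundance": spec.normal_abundance,
                "tumor_fraction": spec.tumor_fraction,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "event_class",
            "variant_seq",
            "locus",
            "tumor_only",
            "gene",
            "tumor_abundance",
            "normal_abundance",
            "tumor_fraction",
        ],
    )
    if not truth.empty and truth["event_id"].duplicated().any():
        raise ValueError("event ids must be unique")
    return truth, tumor_pool, normal_pool


def _build_variant(reference, spec, rng, k, genome_index, tx_index):
    cls = spec.event_class
    if cls in ("snv", "splice", "intron", "repeat", "split") and spec.gene is None:
        raise KeyError(f"event {spec.event_id} of class {cls} needs a target gene")

    if cls == "snv":
        gene = reference.gene(spec.gene)
        tid, T = reference.transcript_of_gene(spec.gene)
        pos = _safe_exon_position(gene, len(T), k)
        old = T[pos]
        new = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(0, 3))) % 4]
        if new == old:  # pragma: no cover - arithmetic above avoids this
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
        seq = T[:pos] + new + T[pos + 1 :]
        gpos = transcript_to_genomic(gene, pos)
        return seq, f"{gene.chrom}:{gpos}"

    if cls == "splice":
        gene = reference.gene(spec.gene)
        if len(gene.exons) < 3:
            raise ValueError(f"splice event needs >=3 exons in {gene.gene_id}")
        keep = [ex for i, ex in enumerate(gene.exons) if i != len(gene.exons) // 2]
        seq = spliced_sequence(reference.chromosomes[gene.chrom], keep, gene.strand)
        skipped = gene.exons[len(gene.exons) // 2]
        return seq, f"{gene.chrom}:{skipped[0]}-{skipped[1]}"

    if cls == "intron":
        gene = reference.gene(spec.gene)
        if len(gene.exons) < 2:
            raise ValueError(f"intron event needs >=2 exons in {gene.gene_id}")
        merged = [(gene.exons[0][0], gene.exons[1][1])] + gene.exons[2:]
        seq = spliced_sequence(reference.chromosomes[gene.chrom], merged, gene.strand)
        intron = (gene.exons[0][1], gene.exons[1][0])
        return seq, f"{gene.chrom}:{intron[0]}-{intron[1]}"

    if cls == "lincrna":
        length = 400
        ivs = reference.intergenic_intervals(min_len=length + 200)
        if not ivs:
            raise ValueError("no intergenic interval large enough for a lincRNA event")
        chrom, s, e = ivs[int(rng.integers(0, len(ivs)))]
        mid = (s + e) // 2
        start = max(s + 50, mid - length // 2)
        seq = reference.chromosomes[chrom][start : start + length]
        return seq, f"{chrom}:{start}-{start + length}"

    if cls == "repeat":
        gene = reference.gene(spec.gene)
        tid, T = reference.transcript_of_gene(spec.gene)
        pos = _safe_exon_position(gene, len(T), k + 10)
        for _ in range(200):
            unit = _random_seq(rng, 12)
            insert = unit * 8
            if _smallest_period(unit * 2) != len(unit):
                continue
            if _all_kmers_novel(insert, genome_index, k) and _all_kmers_novel(
                insert, tx_index, k
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a novel tandem-repeat unit")
        seq = T[:pos] + insert + T[pos:]
        gpos = transcript_to_genomic(gene, pos)
        return seq, f"{gene.chrom}:{gpos}"

    if cls == "polya":
        for _ in range(200):
            core = _random_seq(rng, 100)
            if core[-1] == "A" or "A" * 10 in core or "T" * 10 in core:
                continue
            seq = core + "A" * 25
            if _all_kmers_novel(seq, genome_index, k) and _all_kmers_novel(
                seq, tx_index, k
            ):
                return seq, "none"
        raise RuntimeError("could not draw a novel poly-A event core")  # pragma: no cover

    if cls == "split":
        if spec.gene_b is None:
            raise KeyError(f"split event {spec.event_id} needs two genes")
        ga = reference.gene(spec.gene)
        gb = reference.gene(spec.gene_b)
        _, Ta = reference.transcript_of_gene(spec.gene)
        _, Tb = reference.transcript_of_gene(spec.gene_b)
        cut_a = _safe_exon_position(ga, len(Ta), k)
        cut_b = _safe_exon_position(gb, len(Tb), k)
        prefix, suffix = Ta[:cut_a], Tb[cut_b:]
        if len(prefix) < k or len(suffix) < k:
            raise ValueError("split pieces must each be >= k")
        seq = prefix + suffix
        return seq, f"{ga.chrom}:{transcript_to_genomic(ga, cut_a)}|{gb.chrom}:{transcript_to_genomic(gb, cut_b)}"

    if cls == "unmapped":
        for _ in range(500):
            seq = _random_seq(rng, 150)
            if "A" * 10 in seq or "T" * 10 in seq:
                continue
            if _all_kmers_novel(seq, genome_index, k) and _all_kmers_novel(
                seq, tx_index, k
            ):
                return seq, "none"
        raise RuntimeError("could not draw a foreign sequence")  # pragma: no cover

    raise ValueError(f"unknown event class {cls!r}")  # pragma: no cover


def _smallest_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i % p] for i in range(len(s))):
            return p
    return len(s)


def simulate_reads(
    pool,
    n_reads: int,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Sample single-end reads from a transcript pool.

    Transcripts are sampled proportional to abundance x length, start
    positions uniformly, orientation at random (unstranded), substitution
    errors i.i.d. at ``error_rate``. Deterministic for a fixed seed.
    """
    pool = [
        p if isinstance(p, PoolEntry) else PoolEntry(p[0], p[1], float(p[2]))
        for p in pool
    ]
    for p in pool:
        if len(p.sequence) < read_length:
            raise ValueError(
                f"transcript {p.name!r} (length {len(p.sequence)}) is shorter "
                f"than the read length {read_length}"
            )
    rng = np.random.default_rng(seed)
    weights = np.array([p.abundance * len(p.sequence) for p in pool], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("pool has no positive-abundance transcript")
    probs = weights / weights.sum()
    idx = rng.choice(len(pool), size=n_reads, p=probs)
    highs = np.array([len(p.sequence) - read_length + 1 for p in pool])[idx]
    starts = rng.integers(0, highs)
    flips = rng.random(n_reads) < 0.5
    reads = []
    for i in range(n_reads):
        p = pool[idx[i]]
        seq = p.sequence[starts[i] : starts[i] + read_length]
        if flips[i]:
            seq = revcomp(seq)
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if errs.size:
                chars = list(seq)
                for e in errs:
                    chars[e] = "ACGT"[
                        ("ACGT".index(chars[e]) + 1 + int(rng.integers(0, 3))) % 4
                    ]
                seq = "".join(chars)
        reads.append((f"r{i:06d}", seq))
    return reads


@dataclass
class Cohort:
    reference: Reference
    truth: pd.DataFrame
    sheet: pd.DataFrame
    reads: dict  # sample_id -> list of (read_id, sequence)


def simulate_cohort(
    reference: Reference,
    specs,
    n_tumor: int = 10,
    n_normal: int = 10,
    n_reads: int = 20000,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
    k: int = 31,
    outdir=None,
) -> Cohort:
    """Simulate a full tumor/normal cohort with planted events.

    Events with ``tumor_fraction`` < 1 are assigned to a deterministic
    random subset of round(fraction x n_tumor) tumor samples.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s) for s in ss.generate_state(n_tumor + n_normal + 2) % (2**31 - 1)]
    truth, tumor_pool, normal_pool = plant_events(reference, specs, seed=child[0], k=k)

    tumor_ids = [f"tumor{i + 1:02d}" for i in range(n_tumor)]
    normal_ids = [f"normal{i + 1:02d}" for i in range(n_normal)]
    rng = np.random.default_rng(child[1])
    carriers = {}
    for entry in tumor_pool:
        if entry.carrier_fraction < 1.0:
            n_carry = int(round(entry.carrier_fraction * n_tumor))
            chosen = rng.permutation(n_tumor)[:n_carry]
            carriers[entry.name] = {tumor_ids[j] for j in chosen}

    reads, rows = {}, []
    for si, sid in enumerate(tumor_ids + normal_ids):
        is_tumor = si < n_tumor
        pool = [
            e
            for e in (tumor_pool if is_tumor else normal_pool)
            if e.name not in carriers or sid in carriers[e.name]
        ]
        reads[sid] = simulate_reads(
            pool,
            n_reads=n_reads,
            read_length=read_length,
            error_rate=error_rate,
            seed=child[2 + si],
        )
        rows.append(
            {
                "sample_id": sid,
                "condition": "tumor" if is_tumor else "normal",
                "fastq": f"{sid}.fastq" if outdir is not None else "",
            }
        )
    sheet = pd.DataFrame(rows, columns=["sample_id", "condition", "fastq"])

    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        reference.write(outdir)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        kio.write_sample_sheet(outdir / "samples.tsv", sheet)
        for sid in reads:
            kio.write_fastq(outdir / f"{sid}.fastq", reads[sid])
    return Cohort(reference=reference, truth=truth, sheet=sheet, reads=reads)


def default_event_specs(reference: Reference, tumor_fold: float = 4.0):
    """One event of every class on deterministically chosen genes.

    Differential events are expressed ``tumor_fold`` times higher in tumor
    samples (4x by default) against a normal abundance of 1.
    """
    genes = sorted(reference.genes, key=lambda g: g.gene_id)
    if len(genes) < 6:
        raise ValueError("need at least 6 genes for the default event set")
    ga = genes[4]
    gb = next((g for g in genes if g.chrom != ga.chrom), genes[5])
    assignments = {
        "snv": genes[0].gene_id,
        "splice": genes[1].gene_id,
        "intron": genes[2].gene_id,
        "repeat": genes[3].gene_id,
    }
    specs = []
    for cls in EVENT_CLASSES:
        kw = dict(
            event_id=f"ev_{cls}",
            event_class=cls,
            tumor_abundance=tumor_fold,
            normal_abundance=1.0,
        )
        if cls in assignments:
            kw["gene"] = assignments[cls]
        if cls == "split":
            kw["gene"] = ga.gene_id
            kw["gene_b"] = gb.gene_id
        specs.append(EventSpec(**kw))
    return specs
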