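"""Seed-and-extend alignment, poly-A/tandem detection, event classification."""

import numpy as np
import pandas as pd
import pytest

from kmerdiff import annotate as ann
from kmerdiff import kmers as km
from kmerdiff import simulate as sim

from tests.conftest import conditions_of, make_sheet


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAlignContig:
    def test_exact_exonic_substring_unique(self, toy_reference):
        g = toy_reference.genes[0]
        s, e = g.exons[0]
        contig = toy_reference.chromosomes[g.chrom][s + 10 : s + 90]
        aln = ann.align_contig(contig, toy_reference)
        assert aln.status == "unique" and not aln.mismatches
        b = aln.blocks[0]
        assert (b.chrom, b.gstart, b.gend) == (g.chrom, s + 10, s + 90)

    def test_revcomp_gives_same_blocks(self, toy_reference):
        g = toy_reference.genes[0]
        s, _ = g.exons[0]
        contig = toy_reference.chromosomes[g.chrom][s + 10 : s + 90]
        a1 = ann.align_contig(contig, toy_reference)
        a2 = ann.align_contig(km.revcomp(contig), toy_reference)
        assert a1.status == a2.status
        assert a1.blocks[0].gstart == a2.blocks[0].gstart

    def test_junction_contig_spliced_with_intron_gap(self, toy_reference):
        g = next(g for g in toy_reference.genes if g.strand == "+")
        chrom = toy_reference.chromosomes[g.chrom]
        (s1, e1), (s2, e2) = g.exons[0], g.exons[1]
        contig = chrom[e1 - 30 : e1] + chrom[s2 : s2 + 31]
        aln = ann.align_contig(contig, toy_reference)
        assert aln.status == "spliced"
        b1, b2 = sorted(aln.blocks, key=lambda b: b.gstart)
        assert b2.gstart - b1.gend == s2 - e1  # genomic gap equals intron length
        assert b1.chrom == b2.chrom and b1.strand == b2.strand

    def test_snv_contig_unique_with_one_mismatch(self, toy_reference):
        g = toy_reference.genes[0]
        s, e = g.exons[1]
        mid = (s + e) // 2
        chrom = toy_reference.chromosomes[g.chrom]
        contig = chrom[mid - 30 : mid + 31]
        base = chrom[mid]
        swap = "A" if base != "A" else "C"
        contig = contig[:30] + swap + contig[31:]
        aln = ann.align_contig(contig, toy_reference)
        assert aln.status == "unique"
        assert len(aln.mismatches) == 1
        assert aln.mismatches[0][0] == mid

    def test_foreign_contig_unmapped(self, toy_reference):
        rng = np.random.default_rng(99)
        aln = ann.align_contig(_rand(rng, 120), toy_reference)
        assert aln.status == "unmapped" and aln.blocks == []

    def test_fusion_contig_partial_chimeric(self, toy_reference):
        ga = next(g for g in toy_reference.genes if g.chrom == "chr1")
        gb = next(g for g in toy_reference.genes if g.chrom == "chr2")
        ca = toy_reference.chromosomes["chr1"]
        cb = toy_reference.chromosomes["chr2"]
        sa, ea = ga.exons[0]
        sb, eb = gb.exons[0]
        contig = ca[sa + 50 : sa + 80] + cb[sb + 50 : sb + 80]
        aln = ann.align_contig(contig, toy_reference)
        assert aln.status == "partial_chimeric"
        assert len(aln.blocks) == 2
        assert {b.chrom for b in aln.blocks} == {"chr1", "chr2"}

    def test_duplicated_locus_multi(self, toy_reference):
        # a contig occurring at two genomic positions maps as multi
        seg = toy_reference.chromosomes["chr1"][100:160]
        ref2 = sim.Reference(
            chromosomes={"chr1": toy_reference.chromosomes["chr1"] + "N" + seg},
            genes=[],
            transcripts={},
        )
        aln = ann.align_contig(seg, ref2)
        assert aln.status == "multi" and aln.n_genome_hits >= 2

    def test_shorter_than_seed_warns_unmapped(self, toy_reference):
        with pytest.warns(UserWarning):
            aln = ann.align_contig("ACGTACGTAC", toy_reference, seed_length=15)
        assert aln.status == "unmapped"


class TestDetectors:
    @pytest.mark.parametrize(
        "seq,kind,core",
        [
            ("ACGTGGCATGCATG" + "A" * 12, "tail_A", "ACGTGGCATGCATG"),
            ("T" * 12 + "ACGTGGCATGCATG", "head_T", "ACGTGGCATGCATG"),
            ("ACACACACACACAC", "none", "ACACACACACACAC"),
        ],
    )
    def test_polya_run_length_oracle(self, seq, kind, core):
        got_kind, got_core = ann.detect_polya(seq, min_run=10)
        assert (got_kind, got_core) == (kind, core)

    def test_polya_below_min_run(self):
        assert ann.detect_polya("GCGC" + "A" * 9, min_run=10)[0] == "none"

    @pytest.mark.parametrize(
        "seq,period",
        [
            ("ACGACGACG", 3),
            ("AAAAAAAA", 1),
            ("ACGTACGTAC", 4),
            ("ACGTGCATGCCA", None),
        ],
    )
    def test_tandem_examples(self, seq, period):
        assert ann.detect_tandem(seq) == period

    def test_tandem_brute_force_period_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            unit = _rand(rng, int(rng.integers(1, 15)))
            reps = int(rng.integers(2, 5))
            seq = (unit * (reps + 1))[: len(unit) * reps + int(rng.integers(0, len(unit)))]
            got = ann.detect_tandem(seq, max_unit=30)
            # oracle: smallest p such that seq is p-periodic with >=2 copies
            expect = next(
                (
                    p
                    for p in range(1, len(seq) // 2 + 1)
                    if all(seq[i] == seq[i % p] for i in range(len(seq)))
                ),
                None,
            )
            if expect is not None and expect > 30:
                expect = None
            assert got == expect

    def test_tandem_requires_two_full_copies(self):
        assert ann.detect_tandem("ACGTACG") is None or len("ACGTACG") >= 8


class TestClassify:
    def _unique(self, chrom, start, end, mism=()):
        b = ann.Block(chrom, start, end, "+", 0, end - start, list(mism))
        return ann.AlignmentResult("unique", [b], [(g, q) for q, g, *_ in mism], 1)

    def test_snv_precedence(self, toy_reference):
        g = toy_reference.genes[0]
        s, e = g.exons[0]
        aln = self._unique(g.chrom, s + 5, s + 66, mism=[(30, s + 35, "A")])
        assert ann.classify(aln, "none", None, toy_reference) == "SNV"

    def test_intergenic_unique_is_lincrna(self, toy_reference):
        chrom, s, e = toy_reference.intergenic_intervals(500)[0]
        aln = self._unique(chrom, s + 50, s + 150)
        assert ann.classify(aln, "none", None, toy_reference) == "lincRNA"

    def test_mostly_intronic_unique_is_intron(self, toy_reference):
        g = toy_reference.genes[0]
        i_s, i_e = g.introns[0]
        aln = self._unique(g.chrom, i_s - 20, i_e + 20)
        assert ann.classify(aln, "none", None, toy_reference) == "intron"

    def test_two_chromosome_blocks_split(self, toy_reference):
        blocks = [
            ann.Block("chr1", 100, 130, "+", 0, 30),
            ann.Block("chr2", 500, 530, "+", 30, 60),
        ]
        aln = ann.AlignmentResult("partial_chimeric", blocks, [], 0)
        assert ann.classify(aln, "none", None, toy_reference) == "split"

    def test_polya_requires_unmapped_core(self, toy_reference):
        unmapped = ann.AlignmentResult("unmapped", [], [], 0)
        assert ann.classify(unmapped, "tail_A", None, toy_reference) == "polyA"
        assert ann.classify(unmapped, "none", None, toy_reference) == "unmapped"

    def test_tandem_beats_unmapped(self, toy_reference):
        unmapped = ann.AlignmentResult("unmapped", [], [], 0)
        assert ann.classify(unmapped, "none", 12, toy_reference) == "repeat"

    def test_multi_is_repeat(self, toy_reference):
        b = ann.Block("chr1", 0, 60, "+", 0, 60)
        aln = ann.AlignmentResult("multi", [b, b], [], 2)
        assert ann.classify(aln, "none", None, toy_reference) == "repeat"

    def test_exonic_perfect_match_other_or_splice(self, toy_reference):
        g = toy_reference.genes[0]
        s, e = g.exons[0]
        inside = self._unique(g.chrom, s + 5, e - 5)
        assert ann.classify(inside, "none", None, toy_reference) == "other"
        crossing = self._unique(g.chrom, e - 30, e + 30)
        # crosses the exon/intron boundary; half intronic triggers intron rule
        got = ann.classify(crossing, "none", None, toy_reference)
        assert got in ("intron", "splice")

    def test_strand_symmetric_on_real_contigs(self, toy_reference):
        rng = np.random.default_rng(12)
        g = toy_reference.genes[0]
        s, e = g.exons[0]
        contigs = [
            toy_reference.chromosomes[g.chrom][s + 10 : s + 90],
            _rand(rng, 100),
            "ACGATCGGATCG" * 5,
            _rand(rng, 60) + "A" * 15,
        ]
        for c in contigs:
            fwd = ann.annotate_contig(c, toy_reference)[1]
            rev = ann.annotate_contig(km.revcomp(c), toy_reference)[1]
            assert fwd == rev


class TestHostGene:
    def test_block_inside_gene(self, toy_reference):
        g = toy_reference.genes[0]
        s, e = g.span
        aln = ann.AlignmentResult(
            "unique", [ann.Block(g.chrom, s + 10, s + 70, "+", 0, 60)], [], 1
        )
        assert ann.assign_host_gene(aln, toy_reference.genes) == g.gene_id

    def test_overlap_count_oracle_on_split(self, toy_reference):
        ga, gb = toy_reference.genes[0], toy_reference.genes[1]
        blocks = [
            ann.Block(ga.chrom, ga.span[0], ga.span[0] + 40, "+", 0, 40),
            ann.Block(gb.chrom, gb.span[0], gb.span[0] + 21, "+", 40, 61),
        ]
        aln = ann.AlignmentResult("partial_chimeric", blocks, [], 0)
        assert ann.assign_host_gene(aln, toy_reference.genes) == ga.gene_id

    def test_intergenic_block_none(self, toy_reference):
        chrom, s, e = toy_reference.intergenic_intervals(500)[0]
        aln = ann.AlignmentResult(
            "unique", [ann.Block(chrom, s + 10, s + 50, "+", 0, 40)], [], 1
        )
        assert ann.assign_host_gene(aln, toy_reference.genes) is None

    def test_unmapped_none(self, toy_reference):
        aln = ann.AlignmentResult("unmapped", [], [], 0)
        assert ann.assign_host_gene(aln, toy_reference.genes) is None


class TestFlagNeo:
    def _counts(self, tumor, normal):
        sheet = make_sheet(len(tumor), len(normal))
        return (
            pd.Series(list(tumor) + list(normal), index=sheet["sample_id"].values),
            conditions_of(sheet),
        )

    def test_tumor_specific_true(self):
        counts, cond = self._counts([3, 0, 9, 2], [0, 0, 0, 0])
        assert ann.flag_neo(counts, cond) is True

    def test_single_normal_count_false(self):
        counts, cond = self._counts([3, 0, 9, 2], [0, 1, 0, 0])
        assert ann.flag_neo(counts, cond) is False

    def test_all_zero_false(self):
        counts, cond = self._counts([0, 0], [0, 0])
        assert ann.flag_neo(counts, cond) is False

    def test_no_normal_samples_errors(self):
        counts, cond = self._counts([1, 2], [])
        with pytest.raises(ValueError):
            ann.flag_neo(counts, cond)
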