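"""Split-gene detection, novel-isoform trichotomy, and lncRNA triage."""

import pytest
from Bio import SeqIO

from isoforge.models import TranscriptModel, parse_models
from isoforge.refine import (
    call_lncrna,
    classify_novel_isoforms,
    detect_split_genes,
    intron_count_profile,
    lncrna_total,
    novel_grand_total,
    split_gene_counts,
)


def mk(tid, exons, strand="+", gene=None, chrom="chr1"):
    return TranscriptModel(tid, chrom, strand, tuple(exons), gene)


ANNOT = [
    mk("tA", [(1000, 1200), (1500, 1700)], gene="A"),
    mk("tB", [(3000, 3200), (3500, 3700)], gene="B"),
    mk("tC", [(5000, 5200)], gene="C"),
]


class TestSplitGenes:
    def test_read_spanning_two_genes_proposes_merge(self):
        read = mk("r1", [(1000, 1200), (1500, 1700), (3000, 3200), (3500, 3700)])
        props = detect_split_genes([read], ANNOT)
        assert len(props) == 1
        assert props[0].component_genes == frozenset({"A", "B"})
        assert split_gene_counts(props) == {"n_split_genes": 2, "n_merged": 1}

    def test_transitive_component(self):
        r1 = mk("r1", [(1000, 1200), (3000, 3200)])
        r2 = mk("r2", [(3000, 3200), (5000, 5200)])
        props = detect_split_genes([r1, r2], ANNOT)
        assert len(props) == 1
        assert props[0].component_genes == frozenset({"A", "B", "C"})
        assert props[0].supporting_transcripts == frozenset({"r1", "r2"})

    def test_opposite_strand_not_counted(self):
        read = mk("r1", [(1000, 1200), (3000, 3200)], strand="-")
        assert detect_split_genes([read], ANNOT) == []

    def test_overlap_threshold_enforced(self):
        read = mk("r1", [(1190, 1210), (3190, 3210)])  # 10 bp per gene
        assert detect_split_genes([read], ANNOT, min_exonic_overlap=30) == []

    def test_components_partition_genes(self, dataset):
        outdir, truth = dataset
        aln = parse_models(outdir / "alignments.bed", "BED12")
        ann = parse_models(outdir / "annotation.gff3", "GFF3")
        props = detect_split_genes(aln, ann)
        seen = set()
        for p in props:
            assert not (p.component_genes & seen)
            seen |= p.component_genes
        assert {frozenset(c) for c in truth.split_components} == {
            p.component_genes for p in props
        }


class TestNovelIsoforms:
    def test_intronic_call(self):
        novel = mk("n1", [(1250, 1400)])  # inside intron of gene A
        calls, totals = classify_novel_isoforms([novel], [], ANNOT)
        assert calls[0].category == "intronic"
        assert calls[0].nearest_gene == "A"
        assert totals == {"unmapped": 0, "intronic": 1, "intergenic": 0}

    def test_exon_overlap_is_not_novel(self):
        overlapping = mk("n1", [(1100, 1300)])
        calls, totals = classify_novel_isoforms([overlapping], [], ANNOT)
        assert calls == []
        assert novel_grand_total(totals) == 0

    def test_intergenic_and_unmapped(self):
        novel = mk("n1", [(8000, 8500)])
        calls, totals = classify_novel_isoforms([novel], ["u1"], ANNOT)
        assert {c.category for c in calls} == {"intergenic", "unmapped"}
        assert novel_grand_total(totals) == 2

    def test_antisense_exonic_overlap_flagged_intergenic(self):
        anti = mk("n1", [(1100, 1300)], strand="-")
        calls, _ = classify_novel_isoforms([anti], [], ANNOT)
        assert calls[0].category == "intergenic"
        assert calls[0].antisense_flag and calls[0].nearest_gene == "A"

    def test_unaligned_overlapping_aligned_ids_rejected(self):
        novel = mk("n1", [(8000, 8500)])
        with pytest.raises(ValueError):
            classify_novel_isoforms([novel], ["n1"], ANNOT)

    def test_planted_truth_recovery(self, dataset):
        outdir, truth = dataset
        aln = parse_models(outdir / "alignments.bed", "BED12")
        ann = parse_models(outdir / "annotation.gff3", "GFF3")
        seqs = {r.id for r in SeqIO.parse(str(outdir / "isoforms.fasta"), "fasta")}
        unaligned = seqs - {m.transcript_id for m in aln}
        calls, totals = classify_novel_isoforms(aln, unaligned, ann)
        assert {(c.transcript_id, c.category) for c in calls} == set(
            truth.novel_categories.items()
        )
        assert novel_grand_total(totals) == len(truth.novel_categories)


class TestIntronProfile:
    def test_mono_exon_histogram(self):
        ms = [mk(f"m{i}", [(0, 100)]) for i in range(3)]
        h, _ = intron_count_profile(ms, ms)
        assert h == {0: 1.0}

    def test_mixed_histogram(self):
        a = mk("a", [(0, 10), (20, 30)])
        b = mk("b", [(0, 10), (20, 30), (40, 50), (60, 70)])
        h, _ = intron_count_profile([a, b], [a])
        assert h == {1: 0.5, 3: 0.5}

    def test_novel_transcripts_have_fewer_introns(self, dataset):
        outdir, truth = dataset
        aln = parse_models(outdir / "alignments.bed", "BED12")
        novel = [m for m in aln if m.transcript_id in truth.novel_categories]
        h_novel, h_all = intron_count_profile(novel, aln)
        mean = lambda h: sum(k * v for k, v in h.items())
        assert mean(h_novel) < mean(h_all)


class TestLncRna:
    def test_no_orf_is_noncoding(self):
        seq = "TA" * 300  # no ATG anywhere
        calls, venn = call_lncrna({"x": seq}, {"x": True})
        assert calls[0].channel_coding_potential == "noncoding"
        assert calls[0].venn_class == "potential_only"

    def test_long_orf_is_coding(self):
        seq = "GG" + "ATG" + "GCT" * 120 + "TAA" + "GG"
        calls, venn = call_lncrna({"x": seq}, {"x": False}, orf_min_codons=100)
        assert calls[0].channel_coding_potential == "coding"
        assert calls[0].venn_class == "homology_only"

    def test_venn_partition_recovers_input_count(self):
        seqs = {
            "a": "TA" * 200,                       # noncoding
            "b": "ATG" + "GCT" * 150 + "TAA",      # coding
            "c": "TA" * 200,                       # noncoding
            "d": "ATG" + "GCT" * 150 + "TAA",      # coding
        }
        flags = {"a": True, "b": False, "c": False, "d": True}
        calls, venn = call_lncrna(seqs, flags)
        assert sum(venn.values()) == len(seqs)
        assert venn == {
            "homology_only": 1, "potential_only": 1, "both": 1, "neither": 1
        }
        assert lncrna_total(venn) == 3

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError):
            call_lncrna({"x": "ACGT" * 10}, {})

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            call_lncrna({"x": "ACGTX"}, {"x": True})

    def test_planted_noncoding_recovery(self, dataset):
        outdir, truth = dataset
        seqs = {
            r.id: str(r.seq)
            for r in SeqIO.parse(str(outdir / "isoforms.fasta"), "fasta")
            if r.id in truth.novel_categories
        }
        flags = {}
        with open(outdir / "homology.tsv") as fh:
            next(fh)
            for line in fh:
                tid, hit = line.split()
                flags[tid] = bool(int(hit))
        calls, venn = call_lncrna(seqs, flags)
        pred_nc = {c.transcript_id for c in calls if c.channel_coding_potential == "noncoding"}
        assert pred_nc == truth.noncoding_ids
        # with noise-free flags the two channels agree: lncRNA set == "both"
        assert venn["both"] == len(truth.noncoding_ids)
        assert lncrna_total(venn) == len(truth.noncoding_ids)
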