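"""Long-read-driven annotation refinement.

Split-gene detection: a full-length alignment whose exons overlap exonic
sequence of two or more same-strand annotated genes is evidence that those
gene models are fragments of one true gene; merge proposals are the connected
components of the resulting gene-gene support graph.

Novel-isoform trichotomy: an isoform is novel when it (1) does not align to
the genome, (2) lies entirely within an intron of a gene, or (3) aligns to
intergenic space. Isoforms overlapping annotated exons on the same strand are
not novel. Antisense exonic overlaps are reported as intergenic with a flag.

lncRNA triage combines two channels: absence of protein homology (an input
flag table, so a real BLAST run can be slotted in) and absence of coding
potential (no ATG-initiated stop-free reading frame of at least
``orf_min_codons`` codons on either strand).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genetics import NUCLEOTIDES, longest_orf_codons
from .models import Exon, TranscriptModel

NOVEL_CATEGORIES = ("unmapped", "intronic", "intergenic")
VENN_CLASSES = ("homology_only", "potential_only", "both", "neither")


@dataclass(frozen=True)
class MergeProposal:
    component_genes: frozenset[str]
    supporting_transcripts: frozenset[str]
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class NovelIsoformCall:
    transcript_id: str
    category: str
    nearest_gene: str | None = None
    antisense_flag: bool = False


@dataclass(frozen=True)
class LncRnaCall:
    transcript_id: str
    channel_homology: str  # hit / no_hit
    channel_coding_potential: str  # coding / noncoding
    venn_class: str


# ------------------------------------------------------------- intervals ----


def _merge_intervals(intervals: Iterable[Exon]) -> list[Exon]:
    out: list[Exon] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bp(a: Sequence[Exon], b: Sequence[Exon]) -> int:
    """Total overlap between two sorted disjoint interval lists."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class _GeneIndex:
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]  # merged union over isoforms
    span: Exon
    introns: list[Exon]


def _index_annotation(annotation: Sequence[TranscriptModel]) -> list[_GeneIndex]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in annotation:
        if m.gene_id is None:
            raise ValueError(f"annotation transcript {m.transcript_id} lacks a gene_id")
        by_gene.setdefault(m.gene_id, []).append(m)
    out = []
    for gid in sorted(by_gene):
        ms = by_gene[gid]
        exons = _merge_intervals(e for m in ms for e in m.exons)
        span = (exons[0][0], exons[-1][1])
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        out.append(_GeneIndex(gid, ms[0].chrom, ms[0].strand, exons, span, introns))
    return out


# ------------------------------------------------------------ split genes ----


def detect_split_genes(
    alignments: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    min_exonic_overlap: int = 30,
    min_support: int = 1,
) -> list[MergeProposal]:
    genes = _index_annotation(annotation)
    graph = nx.Graph()
    support: dict[frozenset, set[str]] = {}
    for aln in alignments:
        hit = [
            g.gene_id
            for g in genes
            if g.chrom == aln.chrom
            and g.strand == aln.strand
            and _overlap_bp(list(aln.exons), g.exons) >= min_exonic_overlap
        ]
        if len(hit) >= 2:
            for i, ga in enumerate(hit):
                for gb in hit[i + 1 :]:
                    key = frozenset({ga, gb})
                    support.setdefault(key, set()).add(aln.transcript_id)
    for key, txs in support.items():
        if len(txs) >= min_support:
            graph.add_edge(*sorted(key))

    gene_by_id = {g.gene_id: g for g in genes}
    proposals = []
    for comp in nx.connected_components(graph):
        comp_genes = sorted(comp)
        txs = set()
        for key, t in support.items():
            if key <= comp:
                txs |= t
        gs = [gene_by_id[g] for g in comp_genes]
        proposals.append(
            MergeProposal(
                component_genes=frozenset(comp_genes),
                supporting_transcripts=frozenset(txs),
                chrom=gs[0].chrom,
                strand=gs[0].strand,
                start=min(g.span[0] for g in gs),
                end=max(g.span[1] for g in gs),
            )
        )
    proposals.sort(key=lambda p: (p.chrom, p.start))
    return proposals


def split_gene_counts(proposals: Sequence[MergeProposal]) -> dict[str, int]:
    return {
        "n_split_genes": sum(len(p.component_genes) for p in proposals),
        "n_merged": len(proposals),
    }


# ---------------------------------------------------------- novel isoforms ----


def classify_novel_isoforms(
    alignments: Sequence[TranscriptModel],
    unaligned_ids: Iterable[str],
    annotation: Sequence[TranscriptModel],
) -> tuple[list[NovelIsoformCall], dict[str, int]]:
    unaligned = sorted(set(unaligned_ids))
    aligned_ids = {m.transcript_id for m in alignments}
    if set(unaligned) & aligned_ids:
        raise ValueError("unaligned ids overlap alignment ids")
    genes = _index_annotation(annotation)

    calls = [NovelIsoformCall(tid, "unmapped") for tid in unaligned]
    for aln in alignments:
        same = [g for g in genes if g.chrom == aln.chrom and g.strand == aln.strand]
        anti = [g for g in genes if g.chrom == aln.chrom and g.strand != aln.strand]
        if any(_overlap_bp(list(aln.exons), g.exons) > 0 for g in same):
            continue  # matches known exons: not novel
        span = (aln.start, aln.end)
        intron_host = next(
            (
                g
                for g in same
                if any(i[0] <= span[0] and span[1] <= i[1] for i in g.introns)
            ),
            None,
        )
        if intron_host is not None:
            calls.append(NovelIsoformCall(aln.transcript_id, "intronic", intron_host.gene_id))
            continue
        antisense = next(
            (g for g in anti if _overlap_bp(list(aln.exons), g.exons) > 0), None
        )
        calls.append(
            NovelIsoformCall(
                aln.transcript_id,
                "intergenic",
                antisense.gene_id if antisense else None,
                antisense_flag=antisense is not None,
            )
        )
    totals = {c: 0 for c in NOVEL_CATEGORIES}
    for call in calls:
        totals[call.category] += 1
    return calls, totals


def novel_grand_total(totals: Mapping[str, int]) -> int:
    return sum(int(totals.get(c, 0)) for c in NOVEL_CATEGORIES)


def intron_count_profile(
    models_a: Sequence[TranscriptModel], models_b: Sequence[TranscriptModel]
) -> tuple[dict[int, float], dict[int, float]]:
    """Normalized intron-count frequency histograms for two model sets."""

    def hist(models):
        if not models:
            raise ValueError("empty model set")
        counts: dict[int, int] = {}
        for m in models:
            counts[len(m.introns)] = counts.get(len(m.introns), 0) + 1
        n = len(models)
        return {k: v / n for k, v in sorted(counts.items())}

    return hist(models_a), hist(models_b)


# ----------------------------------------------------------------- lncRNA ----


def call_lncrna(
    isoform_sequences: Mapping[str, str],
    homology_flags: Mapping[str, bool],
    orf_min_codons: int = 100,
) -> tuple[list[LncRnaCall], dict[str, int]]:
    """Two-channel lncRNA triage; flags map isoform id -> protein homology hit."""
    missing = set(isoform_sequences) - set(homology_flags)
    if missing:
        raise ValueError(f"homology flags missing for {len(missing)} isoforms")
    calls = []
    for tid in sorted(isoform_sequences):
        seq = isoform_sequences[tid].upper()
        if any(b not in NUCLEOTIDES for b in seq):
            raise ValueError(f"{tid}: non-ACGT characters in sequence")
        coding = longest_orf_codons(seq) >= orf_min_codons
        no_hit = not homology_flags[tid]
        if no_hit and not coding:
            venn = "both"
        elif no_hit:
            venn = "homology_only"
        elif not coding:
            venn = "potential_only"
        else:
            venn = "neither"
        calls.append(
            LncRnaCall(
                transcript_id=tid,
                channel_homology="no_hit" if no_hit else "hit",
                channel_coding_potential="noncoding" if not coding else "coding",
                venn_class=venn,
            )
        )
    return calls, venn_totals_from_calls(calls)


def venn_totals_from_calls(calls: Sequence[LncRnaCall]) -> dict[str, int]:
    totals = {c: 0 for c in VENN_CLASSES}
    for call in calls:
        totals[call.venn_class] += 1
    return totals


def lncrna_total(venn_totals: Mapping[str, int]) -> int:
    """Size of the lncRNA union: flagged by either channel."""
    return sum(int(venn_totals.get(c, 0)) for c in ("homology_only", "potential_only", "both"))


# -------------------------------------------------------------------- I/O ----


def write_merge_proposals(proposals: Sequence[MergeProposal], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["component", "chrom", "strand", "start", "end", "genes", "supports"])
        for i, p in enumerate(proposals, 1):
            w.writerow([f"merge_{i:04d}", p.chrom, p.strand, p.start, p.end,
                        ",".join(sorted(p.component_genes)),
                        ",".join(sorted(p.supporting_transcripts))])


def write_novel_calls(calls: Sequence[NovelIsoformCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "category", "nearest_gene", "antisense"])
        for c in calls:
            w.writerow([c.transcript_id, c.category, c.nearest_gene or "", int(c.antisense_flag)])


def write_lncrna_calls(calls: Sequence[LncRnaCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "homology", "coding_potential", "venn_class"])
        for c in calls:
            w.writerow([c.transcript_id, c.channel_homology, c.channel_coding_potential, c.venn_class])
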