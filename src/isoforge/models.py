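"""Transcript models: GFF3/BED12 I/O, intron-chain collapse, completeness stats.

Internally every model lives in 0-based half-open coordinates; GFF3 is
converted from/to 1-based inclusive and BED12 from/to 0-based half-open at the
I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

Exon = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-block transcript on a reference sequence."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    gene_id: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -math.inf
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted/overlapping")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Exon, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> tuple:
        return (self.chrom, self.strand) + tuple(x for i in self.introns for x in i)


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    max_length: int
    n50: int
    ex90n50: int | None = None


# ---------------------------------------------------------------- parsing ----


def _parse_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            try:
                chrom, chrom_start = f[0], int(f[1])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount/blockSizes/blockStarts disagree")
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            if exons[-1][1] != int(f[2]):
                raise ValueError(f"{path}:{lineno}: blocks do not end at chromEnd")
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def _parse_gff3(path: Path) -> list[TranscriptModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (child.start - 1, child.end)  # GFF3 1-based inclusive -> half-open
            for child in db.children(feat, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"{feat.id}: transcript without exon children")
        gene_id = None
        parents = list(db.parents(feat, featuretype="gene"))
        if parents:
            gene_id = parents[0].id
        elif "gene_id" in feat.attributes:
            gene_id = feat.attributes["gene_id"][0]
        models.append(
            TranscriptModel(feat.id, feat.seqid, feat.strand, tuple(exons), gene_id)
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def parse_models(path: str | Path, fmt: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12 into internal coordinates."""
    path = Path(path)
    if fmt is None:
        fmt = "BED12" if path.suffix.lower() in {".bed", ".bed12"} else "GFF3"
    fmt = fmt.upper()
    if fmt == "BED12":
        return _parse_bed12(path)
    if fmt == "GFF3":
        return _parse_gff3(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda x: (x.chrom, x.start, x.transcript_id)):
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.start) for s, _ in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        m.transcript_id,
                        "0",
                        m.strand,
                        str(m.start),
                        str(m.end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write gene/mRNA/exon rows, 1-based inclusive. Models sharing gene_id are
    grouped under one gene record spanning them."""
    models = list(models)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id or m.transcript_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene, key=lambda g: (by_gene[g][0].chrom, min(m.start for m in by_gene[g]), g)):
            group = sorted(by_gene[gid], key=lambda m: m.transcript_id)
            chrom, strand = group[0].chrom, group[0].strand
            gstart = min(m.start for m in group)
            gend = max(m.end for m in group)
            if any(m.transcript_id == gid for m in group):
                gid = f"{gid}.gene"  # keep gene and mRNA IDs distinct
            fh.write(
                f"{chrom}\t.\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}\n"
            )
            for m in group:
                fh.write(
                    f"{chrom}\t.\tmRNA\t{m.start + 1}\t{m.end}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gid}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{chrom}\t.\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                    )


# --------------------------------------------------------------- collapse ----


def _reciprocal_overlap(a: Exon, b: Exon) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def collapse_by_intron_chain(
    models: Sequence[TranscriptModel],
    fuzz_end: int = 50,
    mono_exon_overlap: float = 0.95,
) -> list[TranscriptModel]:
    """Merge redundant isoforms.

    Multi-exon models with identical intron chains merge when their terminal
    ends differ by at most ``fuzz_end`` (single linkage); the representative
    spans the extremal ends, so the union of exonic bases is unchanged.
    Mono-exon models merge at reciprocal overlap >= ``mono_exon_overlap``.
    """
    multi: dict[tuple, list[TranscriptModel]] = {}
    mono: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        if len(m.exons) > 1:
            multi.setdefault(m.intron_chain, []).append(m)
        else:
            mono.setdefault((m.chrom, m.strand), []).append(m)

    out: list[TranscriptModel] = []

    for chain_members in multi.values():
        ms = sorted(chain_members, key=lambda m: (m.start, m.transcript_id))
        uf = _UnionFind(len(ms))
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if (
                    abs(ms[i].start - ms[j].start) <= fuzz_end
                    and abs(ms[i].end - ms[j].end) <= fuzz_end
                ):
                    uf.union(i, j)
        clusters: dict[int, list[TranscriptModel]] = {}
        for i, m in enumerate(ms):
            clusters.setdefault(uf.find(i), []).append(m)
        for members in clusters.values():
            out.append(_merge_chain_cluster(members))

    for (chrom, strand), members in mono.items():
        ms = sorted(members, key=lambda m: (m.start, m.transcript_id))
        uf = _UnionFind(len(ms))
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if _reciprocal_overlap(ms[i].exons[0], ms[j].exons[0]) >= mono_exon_overlap:
                    uf.union(i, j)
        clusters: dict[int, list[TranscriptModel]] = {}
        for i, m in enumerate(ms):
            clusters.setdefault(uf.find(i), []).append(m)
        for group in clusters.values():
            rep = min(group, key=lambda m: m.transcript_id)
            exon = (min(m.start for m in group), max(m.end for m in group))
            out.append(TranscriptModel(rep.transcript_id, chrom, strand, (exon,), rep.gene_id))

    out.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return out


def _merge_chain_cluster(members: list[TranscriptModel]) -> TranscriptModel:
    rep = min(members, key=lambda m: m.transcript_id)
    if len(members) == 1:
        return rep
    exons = list(rep.exons)
    exons[0] = (min(m.start for m in members), exons[0][1])
    exons[-1] = (exons[-1][0], max(m.end for m in members))
    return TranscriptModel(rep.transcript_id, rep.chrom, rep.strand, tuple(exons), rep.gene_id)


# ------------------------------------------------------------------ stats ----


def _n50(lengths: Sequence[int]) -> int:
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    return ordered[-1]


def compute_stats(
    models: Sequence[TranscriptModel],
    expression: Sequence[float] | None = None,
) -> AssemblyStats:
    """Completeness statistics: N50 and, with an expression vector, Ex90N50
    (N50 of the smallest top-expressed set reaching >= 90% of total TPM)."""
    if not models:
        raise ValueError("no models")
    lengths = [m.length for m in models]
    ex90n50 = None
    if expression is not None:
        expression = list(expression)
        if len(expression) != len(models):
            raise ValueError("expression vector not aligned to models")
        if any(x < 0 for x in expression):
            raise ValueError("negative expression")
        total = sum(expression)
        if total <= 0:
            raise ValueError("all-zero expression")
        order = sorted(
            range(len(models)),
            key=lambda i: (-expression[i], -lengths[i], models[i].transcript_id),
        )
        acc, top = 0.0, []
        for i in order:
            top.append(lengths[i])
            acc += expression[i]
            if acc >= 0.9 * total:
                break
        ex90n50 = _n50(top)
    return AssemblyStats(
        n_transcripts=len(models),
        max_length=max(lengths),
        n50=_n50(lengths),
        ex90n50=ex90n50,
    )
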