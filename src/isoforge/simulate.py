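"""Seeded generator of every pipeline input, with machine-readable planted truth.

The generator emulates a pooled-tissue Iso-Seq experiment over a draft genome
annotation: full-length reads carry a 5' primer, the cDNA insert, a polyA tail
and the reverse complement of the 3' primer; chimeras are two such inserts
fused with internal primer copies; some annotated genes are deliberately
emitted as split fragments; novel isoforms are planted in intergenic and
intronic space (plus reads that do not map at all); loci carry one planted
local splicing event of each of the five types; paralogous coding pairs are
evolved forward to a target synonymous divergence; and a negative-binomial
count matrix provides tissue x replicate expression with shared per-tissue
means. Every planted entity is recorded in a TruthSet that round-trips
through JSON losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import (
    AMINO_ACID,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_SITES,
    codons_of,
    revcomp,
    validate_cds,
)
from .models import TranscriptModel, write_bed12, write_gff3
from .splicing import AsEvent

TISSUE_NAMES = ("root", "stem", "leaf", "flower", "rhizome")

DEFAULT_PRIMER5 = "AAGCAGTGGTATCAACGCAGAGTA"
DEFAULT_PRIMER3 = "CGCCTGAGAGGGTTGATACCACTA"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 40
    n_split_gene_pairs: int = 4
    n_novel_intergenic: int = 8
    n_novel_intronic: int = 4
    n_unmapped: int = 3
    as_events_per_type: dict[str, int] = field(
        default_factory=lambda: {"ES": 3, "IR": 3, "A5": 3, "A3": 3, "AE": 3}
    )
    n_noncoding: int = 6
    n_chimeric: int = 10
    n_non_full_length: int = 16
    n_filtered_short: int = 6
    reads_per_transcript: int = 2
    read_error_rate: float = 0.01
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    polyA_length: int = 30
    noncoding_flip_rate: float = 0.0
    n_paralog_pairs: int = 60
    paralog_n_codons: int = 300
    target_ks: list[float] = field(default_factory=lambda: [0.34])
    counts_dispersion: float = 0.1
    n_tissues: int = 5
    n_replicates: int = 3

    def validate(self) -> None:
        counts = [
            self.n_chromosomes, self.chrom_length, self.n_genes,
            self.n_split_gene_pairs, self.n_novel_intergenic,
            self.n_novel_intronic, self.n_unmapped, self.n_noncoding,
            self.n_chimeric, self.n_non_full_length, self.n_filtered_short,
            self.reads_per_transcript, self.polyA_length,
            self.n_paralog_pairs, self.n_tissues, self.n_replicates,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_genes == 0:
            raise ValueError("zero-gene config")
        if not (0 <= self.read_error_rate < 0.2):
            raise ValueError("read_error_rate must be in [0, 0.2)")
        if any(v < 0 for v in self.as_events_per_type.values()):
            raise ValueError("negative planted event count")
        if any(k < 0 for k in self.target_ks):
            raise ValueError("target_ks must be non-negative")
        n_special = (
            self.n_split_gene_pairs
            + sum(self.as_events_per_type.values())
            + self.n_novel_intronic
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} special loci"
            )
        n_novel = self.n_novel_intergenic + self.n_novel_intronic + self.n_unmapped
        if self.n_noncoding > n_novel:
            raise ValueError("n_noncoding exceeds number of novel isoforms")


@dataclass
class TruthSet:
    read_labels: dict[str, str]
    split_components: list[set[str]]
    novel_categories: dict[str, str]
    planted_events: list[AsEvent]
    noncoding_ids: set[str]
    pair_ks: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "read_labels": dict(sorted(self.read_labels.items())),
            "split_components": [sorted(c) for c in self.split_components],
            "novel_categories": dict(sorted(self.novel_categories.items())),
            "planted_events": [
                {
                    "event_type": e.event_type,
                    "chrom": e.chrom,
                    "strand": e.strand,
                    "anchors": list(e.anchors),
                    "witnesses": sorted(e.witnesses),
                }
                for e in self.planted_events
            ],
            "noncoding_ids": sorted(self.noncoding_ids),
            "pair_ks": dict(sorted(self.pair_ks.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            read_labels=dict(d["read_labels"]),
            split_components=[set(c) for c in d["split_components"]],
            novel_categories=dict(d["novel_categories"]),
            planted_events=[
                AsEvent(
                    e["event_type"], e["chrom"], e["strand"],
                    tuple(e["anchors"]), frozenset(e["witnesses"]),
                )
                for e in d["planted_events"]
            ],
            noncoding_ids=set(d["noncoding_ids"]),
            pair_ks=dict(d["pair_ks"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ------------------------------------------------------------ sequence gen ----


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, n)])


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by uniform sense codons (no stops)."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    idx = rng.integers(0, len(SENSE_CODONS), n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def _coding_sequence(rng: np.random.Generator, length: int, orf_codons: int = 150) -> str:
    """Random sequence embedding an ATG-initiated stop-free ORF."""
    orf_codons = min(orf_codons, (length - 12) // 3 - 1)
    if orf_codons < 110:
        raise ValueError(f"length {length} too short to embed a >=110-codon ORF")
    orf = random_cds(rng, orf_codons) + "TAA"
    pad = length - len(orf)
    left = int(pad // 2)
    return _random_bases(rng, left) + orf + _random_bases(rng, pad - left)


def _noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Sequence with no ATG on either strand (avoids ATG and CAT substrings),
    hence zero coding potential under the ORF rule."""
    out: list[str] = []
    while len(out) < length:
        b = NUCLEOTIDES[rng.integers(0, 4)]
        tail = "".join(out[-2:]) + b
        if tail.endswith(("ATG", "CAT")):
            continue
        out.append(b)
    return "".join(out)


def evolve_paralog_pair(
    cds: str, target_ks: float, rng: np.random.Generator
) -> tuple[str, str, int]:
    """Evolve two descendants from one ancestor by synonymous substitutions.

    Each lineage receives Poisson(S0 * target_ks / 2) synonymous changes
    (S0 = NG86 synonymous sites of the ancestor), placed uniformly over the
    synonymous single-nucleotide changes available in the current sequence;
    substitutions creating stop codons are redrawn. Returns both descendants
    and the realized total synonymous substitution count.
    """
    cds = cds.upper()
    validate_cds(cds)
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    cods0 = codons_of(cds)
    s0 = sum(SYN_SITES[c] for c in cods0)
    if target_ks > 0 and s0 == 0:
        raise ValueError("sequence has no synonymous sites")

    descendants = []
    realized = 0
    for _ in range(2):
        n_events = int(rng.poisson(s0 * target_ks / 2.0)) if target_ks > 0 else 0
        cods = list(cods0)
        applied = 0
        while applied < n_events:
            i = int(rng.integers(len(cods)))
            pos = int(rng.integers(3))
            alt = NUCLEOTIDES[int(rng.integers(4))]
            codon = cods[i]
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS or AMINO_ACID[mutant] != AMINO_ACID[codon]:
                continue
            cods[i] = mutant
            applied += 1
        realized += applied
        descendants.append("".join(cods))
    return descendants[0], descendants[1], realized


# ----------------------------------------------------------- gene builders ----


def _abs_exons(offset: int, lens: list[int], introns: list[int]) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = offset
    for i, L in enumerate(lens):
        exons.append((pos, pos + L))
        pos += L
        if i < len(introns):
            pos += introns[i]
    return tuple(exons)


def _plant_as_locus(
    event_type: str, gene_id: str, chrom: str, strand: str, offset: int,
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], list[TranscriptModel], AsEvent, int]:
    """Build a two-isoform locus carrying exactly one event of the given type.
    Returns (annotation isoforms, long-read isoforms, planted event, end)."""
    t1, t2 = f"{gene_id}_t1", f"{gene_id}_t2"
    wit = frozenset({t1, t2})
    if event_type == "ES":
        base = _abs_exons(offset, [200, 200, 200, 200], [300, 300, 300])
        alt = (base[0], base[2], base[3])
        anchors = (base[0][1], base[1][0], base[1][1], base[2][0])
    elif event_type == "IR":
        base = _abs_exons(offset, [200, 200, 200], [300, 300])
        alt = ((base[0][0], base[1][1]), base[2])
        anchors = (base[0][1], base[1][0])
    elif event_type in ("A5", "A3"):
        base = _abs_exons(offset, [200, 200, 200], [300, 300])
        delta = 48
        # shift the boundary on the transcription-appropriate side
        shift_donor = (event_type == "A5") == (strand == "+")
        if shift_donor:
            # introns share genomic end, differ at genomic start
            alt = ((base[0][0], base[0][1] - delta), base[1], base[2])
            anchors = (base[0][1] - delta, base[0][1], base[1][0])
        else:
            # introns share genomic start, differ at genomic end
            alt = (base[0], (base[1][0] + delta, base[1][1]), base[2])
            anchors = (base[0][1], base[1][0], base[1][0] + delta)
    elif event_type == "AE":
        e0 = (offset, offset + 200)
        ea = (offset + 350, offset + 500)
        eb = (offset + 650, offset + 800)
        e2 = (offset + 950, offset + 1150)
        base = (e0, ea, e2)
        alt = (e0, eb, e2)
        anchors = (e0[1],) + ea + eb + (e2[0],)
    else:
        raise ValueError(f"unknown event type {event_type!r}")

    m1 = TranscriptModel(t1, chrom, strand, base, gene_id)
    m2 = TranscriptModel(t2, chrom, strand, alt, gene_id)
    event = AsEvent(event_type, chrom, strand, anchors, wit)
    end = max(m1.end, m2.end)
    return [m1], [m1, m2], event, end


# ------------------------------------------------------------- main driver ----


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> TruthSet:
    config.validate()
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "paralogs").mkdir(exist_ok=True)
    except OSError as exc:
        raise ValueError(f"outdir not writable: {exc}") from exc
    rng = np.random.default_rng(config.seed)

    # ---- plan loci -----------------------------------------------------
    as_plan = [
        (etype, k)
        for etype in ("ES", "IR", "A5", "A3", "AE")
        for k in range(config.as_events_per_type.get(etype, 0))
    ]
    n_plain = (
        config.n_genes
        - config.n_split_gene_pairs
        - len(as_plan)
        - config.n_novel_intronic
    )

    units: list[tuple[str, int]] = (
        [("split", i) for i in range(config.n_split_gene_pairs)]
        + [("as", i) for i in range(len(as_plan))]
        + [("intronic_host", i) for i in range(config.n_novel_intronic)]
        + [("plain", i) for i in range(n_plain)]
        + [("novel_intergenic", i) for i in range(config.n_novel_intergenic)]
    )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    annotation: list[TranscriptModel] = []
    longread: list[TranscriptModel] = []  # mappable long-read isoforms
    planted_events: list[AsEvent] = []
    split_components: list[set[str]] = []
    novel_categories: dict[str, str] = {}
    painted: list[tuple[str, str, tuple, str]] = []  # (novel id, chrom, exons, strand)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 0 for c in chrom_names}
    gene_counter = 0

    for u, (role, idx) in enumerate(units):
        chrom = chrom_names[u % config.n_chromosomes]
        strand = "+" if rng.random() < 0.5 else "-"
        offset = cursors[chrom] + int(rng.integers(500, 2000))

        if role == "plain":
            gid = f"g{gene_counter:04d}"
            gene_counter += 1
            k = int(rng.integers(1, 7))
            if k == 1:
                lens, intr = [int(rng.integers(400, 900))], []
            else:
                lens = [int(rng.integers(120, 300)) for _ in range(k)]
                intr = [int(rng.integers(100, 500)) for _ in range(k - 1)]
            exons = _abs_exons(offset, lens, intr)
            m = TranscriptModel(f"{gid}_t1", chrom, strand, exons, gid)
            annotation.append(m)
            longread.append(m)
            end = m.end
        elif role == "as":
            gid = f"g{gene_counter:04d}"
            gene_counter += 1
            etype, _ = as_plan[idx]
            ann, lr, event, end = _plant_as_locus(etype, gid, chrom, strand, offset, rng)
            annotation.extend(ann)
            longread.extend(lr)
            planted_events.append(event)
        elif role == "split":
            gid = f"g{gene_counter:04d}"
            gene_counter += 1
            lens = [180] * 6
            intr = [250] * 5
            exons = _abs_exons(offset, lens, intr)
            p1, p2 = f"{gid}_p1", f"{gid}_p2"
            annotation.append(TranscriptModel(f"{p1}_t1", chrom, strand, exons[:3], p1))
            annotation.append(TranscriptModel(f"{p2}_t1", chrom, strand, exons[3:], p2))
            full = TranscriptModel(f"{gid}_full", chrom, strand, exons, gid)
            longread.append(full)
            split_components.append({p1, p2})
            end = exons[-1][1]
        elif role == "intronic_host":
            gid = f"g{gene_counter:04d}"
            gene_counter += 1
            exons = _abs_exons(offset, [250, 250], [1200])
            host = TranscriptModel(f"{gid}_t1", chrom, strand, exons, gid)
            annotation.append(host)
            longread.append(host)
            nid = f"nvi_{idx:04d}"
            novel_exon = ((exons[0][1] + 300, exons[0][1] + 700),)
            novel = TranscriptModel(nid, chrom, strand, novel_exon, nid)
            longread.append(novel)
            novel_categories[nid] = "intronic"
            painted.append((nid, chrom, novel_exon, strand))
            end = exons[-1][1]
        elif role == "novel_intergenic":
            nid = f"nvg_{idx:04d}"
            L = int(rng.integers(400, 800))
            novel_exon = ((offset, offset + L),)
            novel = TranscriptModel(nid, chrom, strand, novel_exon, nid)
            longread.append(novel)
            novel_categories[nid] = "intergenic"
            painted.append((nid, chrom, novel_exon, strand))
            end = offset + L
        else:  # pragma: no cover
            raise AssertionError(role)
        cursors[chrom] = end

    for chrom in chrom_names:
        if cursors[chrom] + 500 > config.chrom_length:
            raise ValueError(
                f"chrom_length={config.chrom_length} too small "
                f"(need > {cursors[chrom] + 500} on {chrom})"
            )

    # ---- unmapped novels and coding/noncoding assignment ---------------
    unmapped_ids = [f"unm_{i:04d}" for i in range(config.n_unmapped)]
    for nid in unmapped_ids:
        novel_categories[nid] = "unmapped"

    novel_ids = sorted(novel_categories)
    pick = rng.choice(len(novel_ids), size=config.n_noncoding, replace=False)
    noncoding_ids = {novel_ids[i] for i in sorted(pick)}

    # ---- genome with painted novel sequences ---------------------------
    genome: dict[str, np.ndarray] = {
        c: rng.integers(0, 4, config.chrom_length).astype(np.uint8)
        for c in chrom_names
    }
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = {b: i for i, b in enumerate("ACGT")}

    designed: dict[str, str] = {}
    for nid, chrom, exons, strand in painted:
        L = sum(e - s for s, e in exons)
        seq = (
            _noncoding_sequence(rng, L)
            if nid in noncoding_ids
            else _coding_sequence(rng, L)
        )
        designed[nid] = seq
        genomic = seq if strand == "+" else revcomp(seq)
        pos = 0
        for s, e in exons:
            chunk = genomic[pos : pos + (e - s)]
            genome[chrom][s:e] = np.array([code_of[b] for b in chunk], dtype=np.uint8)
            pos += e - s
    for nid in unmapped_ids:
        L = int(rng.integers(400, 800))
        designed[nid] = (
            _noncoding_sequence(rng, L)
            if nid in noncoding_ids
            else _coding_sequence(rng, L)
        )

    chrom_seqs = {c: "".join(NUCLEOTIDES[i] for i in genome[c]) for c in chrom_names}

    def spliced(m: TranscriptModel) -> str:
        seq = "".join(chrom_seqs[m.chrom][s:e] for s, e in m.exons)
        return seq if m.strand == "+" else revcomp(seq)

    isoform_seqs: dict[str, str] = {m.transcript_id: spliced(m) for m in longread}
    for nid in unmapped_ids:
        isoform_seqs[nid] = designed[nid]

    # ---- reads ----------------------------------------------------------
    p5, rc3 = config.primer5, revcomp(config.primer3)
    tail = "A" * config.polyA_length

    def with_errors(seq: str) -> str:
        if config.read_error_rate == 0:
            return seq
        arr = list(seq)
        hits = np.nonzero(rng.random(len(arr)) < config.read_error_rate)[0]
        for i in hits:
            choices = [b for b in NUCLEOTIDES if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
        return "".join(arr)

    read_labels: dict[str, str] = {}
    reads: list[tuple[str, str]] = []
    iso_ids = sorted(isoform_seqs)
    n = 0

    def add_read(seq: str, label: str):
        nonlocal n
        rid = f"read_{n:06d}"
        n += 1
        reads.append((rid, with_errors(seq)))
        read_labels[rid] = label

    for tid in iso_ids:
        for _ in range(config.reads_per_transcript):
            add_read(p5 + isoform_seqs[tid] + tail + rc3, "FLNC")
    for _ in range(config.n_chimeric):
        a, b = (iso_ids[int(rng.integers(len(iso_ids)))] for _ in range(2))
        add_read(
            p5 + isoform_seqs[a] + tail + rc3 + p5 + isoform_seqs[b] + tail + rc3,
            "chimeric",
        )
    for i in range(config.n_non_full_length):
        tid = iso_ids[int(rng.integers(len(iso_ids)))]
        if i % 2 == 0:
            seq = p5 + isoform_seqs[tid] + rc3  # no polyA
        else:
            seq = isoform_seqs[tid] + tail + rc3  # no 5' primer
        add_read(seq, "non_full_length")
    for _ in range(config.n_filtered_short):
        add_read(p5 + _random_bases(rng, 80) + tail + rc3, "filtered_short")

    # ---- counts matrix ---------------------------------------------------
    tissues = [
        TISSUE_NAMES[i] if i < len(TISSUE_NAMES) else f"tissue{i + 1}"
        for i in range(config.n_tissues)
    ]
    samples = [f"{t}_r{r + 1}" for t in tissues for r in range(config.n_replicates)]
    counts = simulate_counts(
        rng,
        transcript_ids=iso_ids,
        tissues=tissues,
        n_replicates=config.n_replicates,
        dispersion=config.counts_dispersion,
    )

    # ---- paralog pairs ---------------------------------------------------
    pair_ks: dict[str, float] = {}
    pair_files: dict[str, tuple[str, str]] = {}
    for i in range(config.n_paralog_pairs):
        target = config.target_ks[i % len(config.target_ks)]
        cds = random_cds(rng, config.paralog_n_codons)
        a, b, _ = evolve_paralog_pair(cds, target, rng)
        pid = f"pair_{i:04d}"
        pair_ks[pid] = float(target)
        pair_files[pid] = (a, b)

    # ---- write everything ------------------------------------------------
    SeqIO.write(
        [SeqRecord(Seq(chrom_seqs[c]), id=c, description="") for c in chrom_names],
        str(outdir / "genome.fasta"),
        "fasta",
    )
    write_gff3(annotation, outdir / "annotation.gff3")
    SeqIO.write(
        [SeqRecord(Seq(isoform_seqs[t]), id=t, description="") for t in iso_ids],
        str(outdir / "isoforms.fasta"),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(s), id=rid, description="") for rid, s in reads],
        str(outdir / "reads.fasta"),
        "fasta",
    )
    write_bed12(longread, outdir / "alignments.bed")

    with open(outdir / "homology.tsv", "w") as fh:
        fh.write("transcript_id\thit\n")
        for nid in sorted(novel_categories):
            hit = 0 if nid in noncoding_ids else 1
            if config.noncoding_flip_rate > 0 and rng.random() < config.noncoding_flip_rate:
                hit = 1 - hit
            fh.write(f"{nid}\t{hit}\n")

    with open(outdir / "counts.tsv", "w") as fh:
        fh.write("transcript_id\t" + "\t".join(samples) + "\n")
        for tid in iso_ids:
            fh.write(tid + "\t" + "\t".join(str(c) for c in counts[tid]) + "\n")

    with open(outdir / "grouping.tsv", "w") as fh:
        fh.write("sample\ttissue\treplicate\n")
        for t in tissues:
            for r in range(config.n_replicates):
                fh.write(f"{t}_r{r + 1}\t{t}\t{r + 1}\n")

    for pid, (a, b) in pair_files.items():
        SeqIO.write(
            [
                SeqRecord(Seq(a), id=f"{pid}_a", description=""),
                SeqRecord(Seq(b), id=f"{pid}_b", description=""),
            ],
            str(outdir / "paralogs" / f"{pid}.fasta"),
            "fasta",
        )

    truth = TruthSet(
        read_labels=read_labels,
        split_components=split_components,
        novel_categories=novel_categories,
        planted_events=planted_events,
        noncoding_ids=noncoding_ids,
        pair_ks=pair_ks,
    )
    truth.save(outdir / "truth.json")

    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth


def simulate_counts(
    rng: np.random.Generator,
    transcript_ids: list[str],
    tissues: list[str],
    n_replicates: int,
    dispersion: float = 0.1,
    base_log_mean: float = 4.0,
    tissue_sd: float = 0.7,
) -> dict[str, list[int]]:
    """Negative-binomial counts with shared per-tissue means across replicates.

    mean_{t,tissue} = exp(Normal(base_log_mean, 1)) * exp(Normal(0, tissue_sd));
    replicates draw NB(r = 1/dispersion, mean) around that shared mean.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    out: dict[str, list[int]] = {}
    for tid in transcript_ids:
        base = float(np.exp(rng.normal(base_log_mean, 1.0)))
        row: list[int] = []
        for _t in tissues:
            mu = base * float(np.exp(rng.normal(0.0, tissue_sd)))
            for _r in range(n_replicates):
                if dispersion == 0:
                    row.append(int(rng.poisson(mu)))
                else:
                    r = 1.0 / dispersion
                    row.append(int(rng.negative_binomial(r, r / (r + mu))))
        out[tid] = row
    return out
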