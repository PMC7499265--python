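"""Full-length non-chimeric (FLNC) read classification and library summaries.

A long read is full length when it carries the 5' primer near its start, the
reverse complement of the 3' primer near its end, and a polyA tail immediately
upstream of that 3' primer match. An extra primer copy in the interior marks
the read as a full-length chimera (two cDNA inserts fused at ligation). Reads
below a length cutoff are filtered out before any other call.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .genetics import revcomp

CLASSES = ("FLNC", "full_length_chimeric", "non_full_length", "filtered_short")


@dataclass(frozen=True)
class FlncParams:
    max_mismatch: int = 2
    search_window: int = 100
    min_polyA_run: int = 20
    min_length: int = 300


@dataclass
class FlncRecord:
    read_id: str
    length: int
    has_primer5: bool
    primer5_offset: int | None
    has_primer3: bool
    primer3_offset: int | None
    has_polyA: bool
    polyA_start: int | None
    internal_primer_hits: int
    klass: str
    insert_sequence: str | None


@dataclass
class LibrarySummary:
    library_id: str
    n_reads_of_insert: int = 0
    n_5prime: int = 0
    n_3prime: int = 0
    n_polyA: int = 0
    n_filtered_short: int = 0
    n_non_full_length: int = 0
    n_full_length: int = 0
    n_flnc: int = 0
    mean_flnc_length: int = 0

    FIELDS = (
        "n_reads_of_insert",
        "n_5prime",
        "n_3prime",
        "n_polyA",
        "n_filtered_short",
        "n_non_full_length",
        "n_full_length",
        "n_flnc",
        "mean_flnc_length",
    )


def _hamming_find(seq: str, pattern: str, lo: int, hi: int, max_mm: int) -> int | None:
    """Leftmost lowest-mismatch occurrence of pattern within seq[lo:hi]."""
    k = len(pattern)
    best, best_mm = None, max_mm + 1
    for off in range(lo, min(hi, len(seq)) - k + 1):
        mm = 0
        window = seq[off : off + k]
        for a, b in zip(window, pattern):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best, best_mm = off, mm
            if mm == 0:
                break
    return best


def _count_hits(seq: str, pattern: str, lo: int, hi: int, max_mm: int) -> int:
    """Non-overlapping occurrences of pattern in seq[lo:hi] at <= max_mm."""
    k = len(pattern)
    n, off = 0, lo
    while off <= min(hi, len(seq)) - k:
        mm = sum(1 for a, b in zip(seq[off : off + k], pattern) if a != b)
        if mm <= max_mm:
            n += 1
            off += k
        else:
            off += 1
    return n


def _polyA_run(seq: str, end: int, min_run: int) -> int | None:
    """Start of the longest tail ending at ``end`` that is >= min_run long with
    at most one non-A per 10 bases; None when no qualifying tail exists."""
    non_a = 0
    best = None
    i = end - 1
    while i >= 0:
        if seq[i] != "A":
            non_a += 1
        run = end - i
        if non_a > run // 10:
            break
        if run >= min_run and seq[i] == "A":
            best = i
        i -= 1
    return best


def classify_read(
    read: str,
    primer5: str,
    primer3: str,
    params: FlncParams = FlncParams(),
    read_id: str = "read",
) -> FlncRecord:
    if not read or not primer5 or not primer3:
        raise ValueError("read and primers must be non-empty")
    read = read.upper()
    rc3 = revcomp(primer3.upper())
    primer5 = primer5.upper()
    n = len(read)

    p5 = _hamming_find(read, primer5, 0, params.search_window + len(primer5), params.max_mismatch)
    p3 = _hamming_find(
        read, rc3, max(0, n - params.search_window - len(rc3)), n, params.max_mismatch
    )
    polyA = None
    if p3 is not None:
        polyA = _polyA_run(read, p3, params.min_polyA_run)

    interior_lo = (p5 + len(primer5)) if p5 is not None else 0
    interior_hi = p3 if p3 is not None else n
    internal = 0
    if interior_hi - interior_lo > 0:
        internal = _count_hits(read, primer5, interior_lo, interior_hi, params.max_mismatch)
        internal += _count_hits(read, rc3, interior_lo, interior_hi, params.max_mismatch)

    full_length = p5 is not None and p3 is not None and polyA is not None
    if n < params.min_length:
        klass = "filtered_short"
    elif full_length and internal > 0:
        klass = "full_length_chimeric"
    elif full_length:
        klass = "FLNC"
    else:
        klass = "non_full_length"

    insert = None
    if klass in ("FLNC", "full_length_chimeric"):
        insert = read[p5 + len(primer5) : polyA]

    return FlncRecord(
        read_id=read_id,
        length=n,
        has_primer5=p5 is not None,
        primer5_offset=p5,
        has_primer3=p3 is not None,
        primer3_offset=p3,
        has_polyA=polyA is not None,
        polyA_start=polyA,
        internal_primer_hits=internal,
        klass=klass,
        insert_sequence=insert,
    )


def classify_file(
    path: str | Path,
    primer5: str,
    primer3: str,
    params: FlncParams = FlncParams(),
) -> list[FlncRecord]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [
        classify_read(str(rec.seq), primer5, primer3, params, read_id=rec.id)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def summarize_library(records: Sequence[FlncRecord], library_id: str) -> LibrarySummary:
    if not records:
        raise ValueError("no records to summarize")
    s = LibrarySummary(library_id=library_id, n_reads_of_insert=len(records))
    flnc_lengths = []
    for r in records:
        s.n_5prime += r.has_primer5
        s.n_3prime += r.has_primer3
        s.n_polyA += r.has_polyA
        if r.klass == "filtered_short":
            s.n_filtered_short += 1
        elif r.klass == "non_full_length":
            s.n_non_full_length += 1
        elif r.klass == "full_length_chimeric":
            s.n_full_length += 1
        elif r.klass == "FLNC":
            s.n_full_length += 1
            s.n_flnc += 1
            flnc_lengths.append(len(r.insert_sequence))
    if flnc_lengths:
        s.mean_flnc_length = round(sum(flnc_lengths) / len(flnc_lengths))
    return s


def aggregate_summaries(summaries: Sequence[LibrarySummary]) -> LibrarySummary:
    """Fieldwise totals; mean FLNC length is FLNC-count-weighted."""
    if not summaries:
        raise ValueError("no summaries")
    agg = LibrarySummary(library_id="Total")
    weighted = 0
    for s in summaries:
        for f in LibrarySummary.FIELDS[:-1]:
            setattr(agg, f, getattr(agg, f) + getattr(s, f))
        weighted += s.mean_flnc_length * s.n_flnc
    if agg.n_flnc:
        agg.mean_flnc_length = round(weighted / agg.n_flnc)
    return agg


def write_summaries(summaries: Iterable[LibrarySummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("library_id",) + LibrarySummary.FIELDS)
        for s in summaries:
            w.writerow([s.library_id] + [getattr(s, f) for f in LibrarySummary.FIELDS])


def write_records(records: Iterable[FlncRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["read_id", "length", "klass", "has_primer5", "has_primer3", "has_polyA",
             "internal_primer_hits", "insert_length"]
        )
        for r in records:
            w.writerow(
                [r.read_id, r.length, r.klass, int(r.has_primer5), int(r.has_primer3),
                 int(r.has_polyA), r.internal_primer_hits,
                 len(r.insert_sequence) if r.insert_sequence else ""]
            )
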