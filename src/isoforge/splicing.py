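"""Alternative-splicing event enumeration and summaries.

Five event types are counted, following the SUPPA-style local definitions:

* ES — exon skipping: an internal exon present in one isoform is spliced out
  by a single intron in the other.
* IR — intron retention: one isoform's exonic block covers the other's intron.
* A5 / A3 — alternative 5'/3' splice site: two overlapping introns share one
  boundary, differ at the other, and the variable stretch is exonic in the
  isoform with the shorter intron. Labels are relative to transcription
  direction (the donor is the intron's 5' end).
* AE — alternative (mutually exclusive) exons: two non-overlapping internal
  exons between the same flanking splice sites, each absent from the other
  isoform.

Alternative first/last exons (AF/AL) are detected but reported outside the
five-type totals. Events are deduplicated by (type, chrom, strand, anchors),
so the same local difference witnessed by several isoform pairs counts once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .models import TranscriptModel

FIVE_TYPES = ("ES", "IR", "A5", "A3", "AE")
EXTRA_TYPES = ("AF", "AL")


@dataclass(frozen=True)
class AsEvent:
    event_type: str
    chrom: str
    strand: str
    anchors: tuple[int, ...]
    witnesses: frozenset = field(default_factory=frozenset, compare=False, hash=False)

    @property
    def key(self):
        return (self.event_type, self.chrom, self.strand, self.anchors)


@dataclass
class AsSummary:
    counts: dict[str, int]
    total: int
    percents: dict[str, int]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AsSummary":
        counts = {t: int(counts.get(t, 0)) for t in FIVE_TYPES}
        total = sum(counts.values())
        percents = {
            t: int(
                (Decimal(c) * 100 / Decimal(total)).quantize(0, rounding=ROUND_HALF_UP)
            )
            if total
            else 0
            for t, c in counts.items()
        }
        return cls(counts=counts, total=total, percents=percents)


def _region_exonic(model: TranscriptModel, lo: int, hi: int) -> bool:
    """True when [lo, hi) is entirely covered by the model's exons."""
    pos = lo
    for s, e in model.exons:
        if e <= pos:
            continue
        if s > pos:
            return False
        pos = min(e, hi)
        if pos >= hi:
            return True
    return pos >= hi


def _pair_events(x: TranscriptModel, y: TranscriptModel) -> list[AsEvent]:
    chrom, strand = x.chrom, x.strand
    wit = frozenset({x.transcript_id, y.transcript_id})
    ev: list[AsEvent] = []
    ix, iy = set(x.introns), set(y.introns)

    # ES: internal exon of x spliced out by one intron of y
    for k in range(1, len(x.exons) - 1):
        es, ee = x.exons[k]
        d1 = x.exons[k - 1][1]
        a2 = x.exons[k + 1][0]
        if (d1, a2) in iy:
            ev.append(AsEvent("ES", chrom, strand, (d1, es, ee, a2), wit))

    # IR: exonic block of x strictly covers an intron of y
    for d, a in iy:
        for s, e in x.exons:
            if s < d and a < e:
                ev.append(AsEvent("IR", chrom, strand, (d, a), wit))
                break

    # A5/A3/AF/AL: intron pairs sharing exactly one boundary
    for xi, (s1, e1) in enumerate(x.introns):
        for yi, (s2, e2) in enumerate(y.introns):
            if max(s1, s2) >= min(e1, e2):  # must overlap
                continue
            if e1 == e2 and s1 != s2:
                # variable region [min_s, max_s) upstream of the shared boundary
                short, short_i = (x, xi) if s1 > s2 else (y, yi)
                lo, hi = min(s1, s2), max(s1, s2)
                up_x, up_y = x.exons[xi], y.exons[yi]  # exon upstream of intron
                if _region_exonic(short, lo, hi):
                    label = "A5" if strand == "+" else "A3"
                    ev.append(AsEvent(label, chrom, strand, (lo, hi, e1), wit))
                elif xi == 0 and yi == 0 and min(up_x[1], up_y[1]) <= max(up_x[0], up_y[0]):
                    anch = tuple(sorted((up_x, up_y))[0] + sorted((up_x, up_y))[1]) + (e1,)
                    label = "AF" if strand == "+" else "AL"
                    ev.append(AsEvent(label, chrom, strand, anch, wit))
            elif s1 == s2 and e1 != e2:
                short = x if e1 < e2 else y
                lo, hi = min(e1, e2), max(e1, e2)
                dn_x, dn_y = x.exons[xi + 1], y.exons[yi + 1]
                if _region_exonic(short, lo, hi):
                    label = "A3" if strand == "+" else "A5"
                    ev.append(AsEvent(label, chrom, strand, (s1, lo, hi), wit))
                elif (
                    xi == len(x.introns) - 1
                    and yi == len(y.introns) - 1
                    and min(dn_x[1], dn_y[1]) <= max(dn_x[0], dn_y[0])
                ):
                    anch = (s1,) + tuple(sorted((dn_x, dn_y))[0] + sorted((dn_x, dn_y))[1])
                    label = "AL" if strand == "+" else "AF"
                    ev.append(AsEvent(label, chrom, strand, anch, wit))

    # AE: mutually exclusive internal exons between shared flanking sites
    for k in range(1, len(x.exons) - 1):
        e1 = x.exons[k]
        d = x.exons[k - 1][1]
        a = x.exons[k + 1][0]
        for j in range(1, len(y.exons) - 1):
            e2 = y.exons[j]
            if y.exons[j - 1][1] != d or y.exons[j + 1][0] != a:
                continue
            if max(e1[0], e2[0]) < min(e1[1], e2[1]):  # overlapping -> not AE
                continue
            if e1 in set(y.exons) or e2 in set(x.exons):
                continue
            first, second = sorted((e1, e2))
            ev.append(AsEvent("AE", chrom, strand, (d,) + first + second + (a,), wit))
    return ev


def enumerate_events(
    locus_isoforms: Sequence[TranscriptModel],
    include_extra: bool = False,
) -> list[AsEvent]:
    """All deduplicated local AS events among the isoforms of one locus."""
    if len(locus_isoforms) < 2:
        return []
    chroms = {m.chrom for m in locus_isoforms}
    strands = {m.strand for m in locus_isoforms}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("locus isoforms must share chromosome and strand")
    seen: dict[tuple, AsEvent] = {}
    for i, x in enumerate(locus_isoforms):
        for y in locus_isoforms[i + 1 :]:
            for ev in _pair_events(x, y) + _pair_events(y, x):
                if ev.event_type in EXTRA_TYPES and not include_extra:
                    continue
                if ev.key in seen:
                    old = seen[ev.key]
                    seen[ev.key] = AsEvent(
                        ev.event_type, ev.chrom, ev.strand, ev.anchors,
                        old.witnesses | ev.witnesses,
                    )
                else:
                    seen[ev.key] = ev
    return sorted(seen.values(), key=lambda e: (e.chrom, e.anchors, e.event_type))


def summarize_events(events: Iterable[AsEvent]) -> AsSummary:
    counts = {t: 0 for t in FIVE_TYPES}
    for ev in events:
        if ev.event_type in counts:
            counts[ev.event_type] += 1
    return AsSummary.from_counts(counts)


def tissue_isoform_shares(per_tissue_counts: Mapping[str, int]) -> dict[str, float]:
    """Percent of splicing isoforms per tissue, half-up rounded to 2 dp."""
    if any(c < 0 for c in per_tissue_counts.values()):
        raise ValueError("negative count")
    total = sum(per_tissue_counts.values())
    if total == 0:
        raise ValueError("all-zero counts")
    return {
        t: float(
            (Decimal(c) * 100 / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for t, c in per_tissue_counts.items()
    }


def write_events(events: Iterable[AsEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_type", "chrom", "strand", "anchors", "witnesses"])
        for ev in events:
            w.writerow(
                [ev.event_type, ev.chrom, ev.strand,
                 ",".join(map(str, ev.anchors)), ",".join(sorted(ev.witnesses))]
            )


def write_summary(summary: AsSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_type", "count", "percent"])
        for t in FIVE_TYPES:
            w.writerow([t, summary.counts[t], summary.percents[t]])
        w.writerow(["total", summary.total, 100 if summary.total else 0])
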