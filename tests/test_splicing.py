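"""Five-type AS event enumeration, deduplication, and summary layouts."""

import numpy as np
import pytest

from isoforge.models import TranscriptModel, parse_models
from isoforge.pipeline import group_loci
from isoforge.splicing import (
    AsSummary,
    enumerate_events,
    summarize_events,
    tissue_isoform_shares,
)


def mk(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(tid, chrom, strand, tuple(exons))


# -------------------------------------------------------------------------
# Independent brute-force oracle: works on per-base exonic sets and raw
# intron pairs, straight from the event definitions.
# -------------------------------------------------------------------------


def _bases(m):
    return {p for s, e in m.exons for p in range(s, e)}


def _oracle_pair(x, y, strand):
    evs = set()
    ix, iy = set(x.introns), set(y.introns)
    bx, by = _bases(x), _bases(y)
    for a, b, ia, ib, ba in ((x, y, ix, iy, bx), (y, x, iy, ix, by)):
        # ES
        for k in range(1, len(a.exons) - 1):
            d1 = a.exons[k - 1][1]
            a2 = a.exons[k + 1][0]
            if (d1, a2) in ib:
                evs.add(("ES", (d1,) + a.exons[k] + (a2,)))
        # IR: intron of b strictly inside one exonic block of a
        for d, aa_ in ib:
            if d - 1 in ba and aa_ in ba and set(range(d, aa_)) <= ba:
                evs.add(("IR", (d, aa_)))
        # A5/A3
        for s1, e1 in ia:
            for s2, e2 in ib:
                if max(s1, s2) >= min(e1, e2):
                    continue
                if e1 == e2 and s1 != s2:
                    shorter_bases = ba if s1 > s2 else _bases(b)
                    region = set(range(min(s1, s2), max(s1, s2)))
                    if region <= shorter_bases:
                        label = "A5" if strand == "+" else "A3"
                        evs.add((label, (min(s1, s2), max(s1, s2), e1)))
                elif s1 == s2 and e1 != e2:
                    shorter_bases = ba if e1 < e2 else _bases(b)
                    region = set(range(min(e1, e2), max(e1, e2)))
                    if region <= shorter_bases:
                        label = "A3" if strand == "+" else "A5"
                        evs.add((label, (s1, min(e1, e2), max(e1, e2))))
        # AE
        for k in range(1, len(a.exons) - 1):
            d = a.exons[k - 1][1]
            q = a.exons[k + 1][0]
            for j in range(1, len(b.exons) - 1):
                if b.exons[j - 1][1] != d or b.exons[j + 1][0] != q:
                    continue
                e1, e2 = a.exons[k], b.exons[j]
                if set(range(*e1)) & set(range(*e2)):
                    continue
                if e1 in b.exons or e2 in a.exons:
                    continue
                lo, hi = sorted((e1, e2))
                evs.add(("AE", (d,) + lo + hi + (q,)))
    return evs


def oracle_events(isoforms):
    evs = set()
    strand = isoforms[0].strand
    for i, x in enumerate(isoforms):
        for y in isoforms[i + 1 :]:
            evs |= _oracle_pair(x, y, strand)
    return evs


def _keys(events):
    return {(e.event_type, e.anchors) for e in events}


class TestConstructedLoci:
    def test_cassette_exon_yields_one_es(self):
        x = mk("x", [(0, 100), (200, 300), (400, 500)])
        y = mk("y", [(0, 100), (400, 500)])
        evs = enumerate_events([x, y])
        assert [e.event_type for e in evs] == ["ES"]
        assert evs[0].anchors == (100, 200, 300, 400)

    def test_retained_intron_yields_one_ir(self):
        x = mk("x", [(0, 300)])
        y = mk("y", [(0, 100), (200, 300)])
        evs = enumerate_events([x, y])
        assert [e.event_type for e in evs] == ["IR"]
        assert evs[0].anchors == (100, 200)

    def test_alternative_donor_and_acceptor_labels(self):
        # introns share the genomic end, differ at start
        x = mk("x", [(0, 100), (200, 300)])
        y = mk("y", [(0, 150), (200, 300)])
        (ev,) = enumerate_events([x, y])
        assert ev.event_type == "A5"
        x2 = mk("x", [(0, 100), (200, 300)], strand="-")
        y2 = mk("y", [(0, 150), (200, 300)], strand="-")
        (ev2,) = enumerate_events([x2, y2])
        assert ev2.event_type == "A3"

    def test_mutually_exclusive_exons(self):
        x = mk("x", [(0, 100), (200, 300), (600, 700)])
        y = mk("y", [(0, 100), (400, 500), (600, 700)])
        (ev,) = enumerate_events([x, y])
        assert ev.event_type == "AE"
        assert ev.anchors == (100, 200, 300, 400, 500, 600)

    def test_three_isoform_locus_matches_brute_force(self):
        x = mk("x", [(0, 100), (200, 300), (400, 500)])
        y = mk("y", [(0, 100), (400, 500)])  # ES vs x
        z = mk("z", [(0, 100), (200, 330), (400, 500)])  # A3 vs x (on +)
        isoforms = [x, y, z]
        assert _keys(enumerate_events(isoforms)) == oracle_events(isoforms)

    def test_dedup_is_order_invariant(self):
        x = mk("x", [(0, 100), (200, 300), (400, 500)])
        y = mk("y", [(0, 100), (400, 500)])
        z = mk("z", [(0, 100), (200, 300), (400, 520)])
        a = _keys(enumerate_events([x, y, z]))
        b = _keys(enumerate_events([z, x, y]))
        assert a == b

    def test_mixed_strand_locus_rejected(self):
        with pytest.raises(ValueError):
            enumerate_events([mk("x", [(0, 100), (200, 300)]),
                              mk("y", [(0, 100), (200, 300)], strand="-")])

    def test_strand_flip_swaps_a5_a3_and_fixes_others(self):
        loci = [
            [mk("x", [(0, 100), (200, 300), (400, 500)]), mk("y", [(0, 100), (400, 500)])],
            [mk("x", [(0, 300)]), mk("y", [(0, 100), (200, 300)])],
            [mk("x", [(0, 100), (200, 300)]), mk("y", [(0, 150), (200, 300)])],
            [mk("x", [(0, 100), (200, 300)]), mk("y", [(0, 100), (250, 300)])],
        ]
        swap = {"A5": "A3", "A3": "A5"}
        for locus in loci:
            fwd = sorted(e.event_type for e in enumerate_events(locus))
            flipped = [
                TranscriptModel(m.transcript_id, m.chrom, "-", m.exons) for m in locus
            ]
            rev = sorted(
                swap.get(e.event_type, e.event_type) for e in enumerate_events(flipped)
            )
            assert fwd == rev


class TestRandomLociAgainstOracle:
    def test_random_small_loci(self):
        rng = np.random.default_rng(42)
        grid = list(range(0, 2000, 50))
        for trial in range(150):
            n_iso = int(rng.integers(2, 5))
            isoforms = []
            for i in range(n_iso):
                n_exons = int(rng.integers(1, 5))
                bounds = sorted(rng.choice(len(grid), size=2 * n_exons, replace=False))
                exons = [(grid[bounds[2 * k]], grid[bounds[2 * k + 1]]) for k in range(n_exons)]
                isoforms.append(mk(f"iso{i}", exons))
            assert _keys(enumerate_events(isoforms)) == oracle_events(isoforms), trial

    def test_planted_synthetic_loci_match_oracle_and_truth(self, dataset):
        outdir, truth = dataset
        models = parse_models(outdir / "alignments.bed", "BED12")
        all_keys = set()
        for locus in group_loci(models):
            if len(locus) < 2 or len(locus) > 4:
                continue
            got = enumerate_events(locus)
            assert _keys(got) == oracle_events(locus)
            all_keys |= {e.key for e in got}
        assert all_keys == {e.key for e in truth.planted_events}


class TestSummaries:
    def test_single_event_type_is_100_percent(self):
        x = mk("x", [(0, 300)])
        y = mk("y", [(0, 100), (200, 300)])
        s = summarize_events(enumerate_events([x, y]))
        assert s.total == 1
        assert s.percents["IR"] == 100
        assert sum(s.percents.values()) == 100

    def test_summary_from_counts_totals(self):
        s = AsSummary.from_counts({"A5": 10, "A3": 20, "AE": 30, "IR": 25, "ES": 15})
        assert s.total == 100
        assert sum(s.counts.values()) == s.total

    def test_tissue_share_single_tissue(self):
        assert tissue_isoform_shares({"flower": 42}) == {"flower": 100.0}

    def test_tissue_share_rejects_zero_total(self):
        with pytest.raises(ValueError):
            tissue_isoform_shares({"a": 0, "b": 0})
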