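"""NG86 Ka/Ks estimation, peak detection, and WGD dating."""

import math
from functools import lru_cache
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoforge.kswgd import (
    KsEstimate,
    jukes_cantor,
    ks_distribution_peak,
    ks_to_time,
    ng86,
)
from isoforge.simulate import evolve_paralog_pair, random_cds

# -------------------------------------------------------------------------
# Exhaustive oracle: translates with Biopython, counts sites per position by
# explicit mutation, and enumerates substitution pathways by recursion.
# -------------------------------------------------------------------------

from Bio.Seq import Seq


@lru_cache(maxsize=None)
def _aa(codon):
    return str(Seq(codon).translate())


SENSE = [c for c in ("".join(t) for t in product("ACGT", repeat=3)) if _aa(c) != "*"]


def oracle_syn_sites(codon):
    s = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            m = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(m) != "*" and _aa(m) == _aa(codon):
                s += 1 / 3
    return s


def oracle_paths(c1, c2):
    """All stop-free substitution pathways as (syn, nonsyn) tuples."""
    if c1 == c2:
        return [(0, 0)]
    paths = []
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        nxt = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if _aa(nxt) == "*":
            continue
        step = (1, 0) if _aa(nxt) == _aa(c1) else (0, 1)
        for syn, nsyn in oracle_paths(nxt, c2):
            paths.append((step[0] + syn, step[1] + nsyn))
    return paths


def oracle_ng86(seq1, seq2):
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        paths = oracle_paths(c1, c2)
        if not paths:
            continue
        S += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
        N += 3 - (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
        used += 1
    ps, pn = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * ps / 3) if ps < 0.75 else math.nan
    ka = -0.75 * math.log(1 - 4 * pn / 3) if pn < 0.75 else math.nan
    return S, N, Sd, Nd, ks, ka, used


def random_codon_pairs(rng, n_codons):
    s1 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n_codons))
    s2 = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n_codons))
    return s1, s2


class TestNg86:
    def test_identical_sequences(self):
        e = ng86("ATGGGGAAA", "ATGGGGAAA")
        assert e.Sd == e.Nd == 0
        assert e.ks == 0 and e.ka == 0

    def test_single_synonymous_change(self):
        # GGG->GGA at a third position: 1 syn site per Gly codon, ps = 0.5
        e = ng86("GGGGGG", "GGAGGG")
        assert e.S == pytest.approx(2.0)
        assert e.Sd == pytest.approx(1.0)
        assert e.ps == pytest.approx(0.5)
        assert e.ks == pytest.approx(0.8240, abs=1e-4)
        assert e.ka == 0.0

    def test_single_nonsynonymous_change(self):
        e = ng86("GGGGGG", "AGGGGG")  # Gly -> Arg
        assert e.Sd == 0 and e.Nd == pytest.approx(1.0)
        assert e.ks == 0.0
        assert e.pn == pytest.approx(1.0 / e.N)
        assert e.ka == pytest.approx(jukes_cantor(1.0 / e.N))

    def test_site_conservation_and_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = random_codon_pairs(rng, 10)
            e1, e2 = ng86(a, b), ng86(b, a)
            assert e1.S + e1.N == pytest.approx(3 * e1.n_codons_used)
            for f in ("S", "N", "Sd", "Nd", "n_codons_used"):
                assert getattr(e1, f) == pytest.approx(getattr(e2, f))

    def test_matches_exhaustive_enumerator(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = random_codon_pairs(rng, 10)
            mine = ng86(a, b)
            S, N, Sd, Nd, ks, ka, used = oracle_ng86(a, b)
            assert mine.S == pytest.approx(S)
            assert mine.N == pytest.approx(N)
            assert mine.Sd == pytest.approx(Sd)
            assert mine.Nd == pytest.approx(Nd)
            assert mine.n_codons_used == used
            if math.isnan(ks):
                assert mine.ks_saturated
            else:
                assert mine.ks == pytest.approx(ks)

    def test_matches_biopython_reference(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(5)
        for _ in range(10):
            cds = random_cds(rng, 60)
            a, b, _ = evolve_paralog_pair(cds, 0.4, rng)
            mine = ng86(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.ks == pytest.approx(ds, abs=1e-9)
            assert mine.ka == pytest.approx(dn, abs=1e-9)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86("ATGTAAGGG", "ATGTAAGGG")

    def test_gapped_codons_dropped_pairwise(self):
        e = ng86("GGG---GGA", "GGGAAAGGG")
        assert e.n_codons_used == 2
        assert e.n_codons_dropped == 1

    @given(st.floats(0.001, 0.74))
    @settings(max_examples=50, deadline=None)
    def test_jc_correction_monotone_and_above_p(self, p):
        d = jukes_cantor(p)
        assert d > p  # correction inflates observed proportions
        assert jukes_cantor(p * 0.5) < d


class TestPeakAndDating:
    def test_point_mass_mode(self):
        vals = [0.2] * 50
        peak = ks_distribution_peak(vals)
        assert peak.mode_ks == pytest.approx(0.2)

    def test_bimodal_mixture_prefers_heavy_mode(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate(
            [rng.normal(0.1, 0.02, 100), rng.normal(0.6, 0.05, 400)]
        ).clip(0.001)
        peak = ks_distribution_peak(list(vals))
        assert abs(peak.mode_ks - 0.6) < 0.1

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(0.34, 0.05, 500))
        peak = ks_distribution_peak(list(vals))
        assert abs(peak.mode_ks - 0.34) < 0.03

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ks_distribution_peak([0.3] * 10)

    def test_time_conversion(self):
        assert round(ks_to_time(0.34, 6.5e-9) / 1e6, 2) == 26.15
        assert ks_to_time(0.0, 1e-9) == 0.0
        assert ks_to_time(0.5, 1e-8) == pytest.approx(2 * ks_to_time(0.25, 1e-8))


class TestEvolution:
    def test_zero_target_is_identity(self):
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 100)
        a, b, n = evolve_paralog_pair(cds, 0.0, rng)
        assert a == b == cds and n == 0

    def test_realized_counts_ordered_in_target(self):
        cds = random_cds(np.random.default_rng(0), 300)
        _, _, n_low = evolve_paralog_pair(cds, 0.1, np.random.default_rng(9))
        _, _, n_high = evolve_paralog_pair(cds, 0.6, np.random.default_rng(9))
        assert n_low < n_high

    def test_descendants_preserve_protein(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(2)
        cds = random_cds(rng, 120)
        a, b, _ = evolve_paralog_pair(cds, 0.5, rng)
        assert str(Seq(a).translate()) == str(Seq(cds).translate())
        assert str(Seq(b).translate()) == str(Seq(cds).translate())

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            evolve_paralog_pair("ATGTAAGGG", 0.1, np.random.default_rng(0))
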