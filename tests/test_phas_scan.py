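"""The sliding-window scan: hypergeometric test, window arithmetic, phase
scoring, and locus calling."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phaswindow import (GenomicInterval, PhaseWindow, ScanParams,
                        build_covered_regions, call_regions, collapse,
                        compare_regions, enumerate_windows,
                        on_phase_positions, phase_score, phasing_pvalue,
                        scan)

from conftest import mk_read


def exact_upper_tail(N, m, n, k):
    """Independent oracle: exact integer-arithmetic tail sum."""
    total = comb(N, n)
    num = sum(comb(m, j) * comb(N - m, n - j)
              for j in range(k, min(n, m) + 1))
    return num / total


def enumerated_upper_tail(N, m, n, k):
    """Second oracle: literal enumeration of all C(N, n) occupancy subsets
    (tiny N only)."""
    hits = 0
    total = 0
    on_phase = set(range(m))
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(on_phase.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestPhasingPvalue:
    def test_matches_subset_enumeration_small_n(self):
        for N in (4, 7, 10):
            for m in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, m) + 1):
                        expect = enumerated_upper_tail(N, m, n, k)
                        assert phasing_pvalue(N, m, n, k) == \
                            pytest.approx(expect, rel=1e-9)

    def test_window_sized_case_closed_form(self):
        # three occupied positions, all on-phase, in a default window
        expect = comb(20, 3) * comb(400, 0) / comb(420, 3)
        assert phasing_pvalue(420, 20, 3, 3) == pytest.approx(expect, rel=1e-12)

    def test_k_zero_is_full_tail(self):
        assert phasing_pvalue(420, 20, 10, 0) == 1.0

    def test_all_positions_occupied_is_degenerate(self):
        for k in range(0, 8):
            assert phasing_pvalue(40, 7, 40, k) == pytest.approx(1.0)

    def test_invalid_quadruple_raises(self):
        with pytest.raises(ValueError):
            phasing_pvalue(10, 5, 3, 4)  # k > n
        with pytest.raises(ValueError):
            phasing_pvalue(10, 11, 3, 1)  # m > N

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_monotone_in_on_phase_occupancy(self, data):
        # adding an occupied on-phase position never increases the p-value
        N = data.draw(st.integers(4, 200))
        m = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N - 1))
        k = data.draw(st.integers(0, min(n, m) - (1 if min(n, m) else 0)))
        p0 = phasing_pvalue(N, m, n, k)
        p1 = phasing_pvalue(N, m, n + 1, k + 1)
        assert p1 <= p0 + 1e-12


class TestWindows:
    def test_interval_union(self):
        rs = collapse([mk_read(start=100), mk_read(start=110)])
        assert build_covered_regions(rs) == [GenomicInterval("Chr01", 100, 131)]

    def test_disjoint_reads_two_regions(self):
        rs = collapse([mk_read(start=100), mk_read(start=200)])
        assert len(build_covered_regions(rs)) == 2

    def test_bookended_reads_merge(self):
        rs = collapse([mk_read(start=100), mk_read(start=121)])
        assert build_covered_regions(rs) == [GenomicInterval("Chr01", 100, 142)]

    @pytest.mark.parametrize("length,n_windows", [(210, 10), (21, 1), (30, 2)])
    def test_window_counts(self, length, n_windows):
        region = GenomicInterval("Chr01", 42, 42 + length)
        wins = enumerate_windows(region)
        assert len(wins) == n_windows
        assert all(len(w) == 210 for w in wins)
        assert wins[0].start == 42

    def test_window_count_property_multiples_of_21(self):
        # over many random region sets, windows = covered length / 21
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_regions = rng.integers(1, 8)
            lengths = 21 * rng.integers(1, 40, size=n_regions)
            pos = 0
            total = 0
            for L in lengths:
                pos += int(rng.integers(22, 300))
                region = GenomicInterval("Chr01", pos, pos + int(L))
                total += len(enumerate_windows(region))
                pos += int(L)
            assert total == int(lengths.sum()) // 21


class TestOnPhasePositions:
    def test_register_one(self):
        plus, minus = on_phase_positions(
            PhaseWindow(GenomicInterval("Chr01", 0, 210), 1))
        assert plus == list(range(0, 210, 21))
        assert minus == list(range(19, 210, 21))

    @pytest.mark.parametrize("w,x", [(0, 1), (0, 21), (84, 5), (1000, 13)])
    def test_brute_force_enumeration(self, w, x):
        params = ScanParams()
        plus, minus = on_phase_positions(
            PhaseWindow(GenomicInterval("Chr01", w, w + 210), x), params)
        want_plus = [p for p in range(w, w + 210)
                     if p % 21 == (w + x - 1) % 21]
        want_minus = [q for q in range(w, w + 210)
                      if q % 21 == (w + x - 1 - 2) % 21]
        assert plus == want_plus and minus == want_minus
        assert len(plus) == len(minus) == 10


class TestPhaseScore:
    def test_two_cycles_scores_zero(self):
        assert phase_score(1e6, 0.0, 2) == 0.0

    def test_closed_form(self):
        assert phase_score(10, 0, 3) == pytest.approx(math.log(101))
        assert phase_score(10, 0, 5) == pytest.approx(3 * math.log(101))

    def test_monotone_grid(self):
        for k in (3, 5, 9):
            for U in (0.0, 5.0, 50.0):
                scores = [phase_score(P, U, k) for P in (1, 2, 4, 8, 16)]
                assert all(b > a for a, b in zip(scores, scores[1:]))
            for P in (1.0, 10.0):
                scores = [phase_score(P, U, k) for U in (0, 1, 5, 25)]
                assert all(b < a for a, b in zip(scores, scores[1:]))

    def test_negative_abundance_raises(self):
        with pytest.raises(ValueError):
            phase_score(-1, 0, 3)


def _phased_locus_reads(chrom="Chr01", start=1050, cycles=(0, 1, 2, 3, 4, 5),
                        count=10, shift=0):
    reads = []
    for j in cycles:
        p = start + 21 * j + shift
        reads.append(mk_read(chrom=chrom, start=p, strand="+", count=count))
        reads.append(mk_read(chrom=chrom, start=p - 2, strand="-",
                             count=count))
    return reads


class TestScan:
    def test_planted_locus_is_significant(self):
        rs = collapse(_phased_locus_reads())
        hits = scan(rs)
        assert hits
        assert min(h.test.p_value for h in hits) < 1e-6
        # all hits lie on the planted phase track
        for h in hits:
            phase0 = (h.window.interval.start + h.window.register - 1) % 21
            assert phase0 == 1050 % 21

    def test_empty_input(self):
        assert scan(collapse([])) == []

    def test_uniform_reads_yield_no_hits(self):
        rng = np.random.default_rng(1)
        reads = [mk_read(start=int(p), strand=("+", "-")[int(s)])
                 for p, s in zip(rng.integers(0, 50_000, 600),
                                 rng.integers(0, 2, 600))]
        assert len(scan(collapse(reads))) <= 2

    def test_translation_invariance(self):
        rs0 = collapse(_phased_locus_reads(shift=0))
        rs1 = collapse(_phased_locus_reads(shift=21 * 40))
        h0, h1 = scan(rs0), scan(rs1)
        assert [h.test for h in h0] == [h.test for h in h1]
        assert [h.window.interval.start + 21 * 40 for h in h0] == \
            [h.window.interval.start for h in h1]


class TestCallRegions:
    def test_adjacent_windows_one_region(self):
        rs = collapse(_phased_locus_reads(cycles=range(12)))
        hits = scan(rs)
        assert len({h.window.interval.start for h in hits}) > 1
        regions = call_regions(hits, rs)
        assert len(regions) == 1
        reg = regions[0]
        assert reg.rank == 1
        # trimmed to the outermost on-phase starts (+21 right)
        assert reg.interval.start == 1050 - 2
        assert reg.interval.end == 1050 + 11 * 21 + 21

    def test_top_k_keeps_higher_score(self):
        reads = (_phased_locus_reads(start=1050, count=100)
                 + _phased_locus_reads(start=9003, cycles=range(4), count=2))
        rs = collapse(reads)
        hits = scan(rs)
        all_regions = call_regions(hits, rs)
        assert len(all_regions) == 2
        top = call_regions(hits, rs, ScanParams(top_k=1))
        assert len(top) == 1
        assert top[0].phase_score == max(r.phase_score for r in all_regions)
        assert top[0].interval.start == 1048

    def test_recovery_on_default_simulation(self, sim7, phasing_set7,
                                            regions7):
        metrics = compare_regions(
            [r.interval for r in regions7],
            [t.interval for t in sim7.truth.loci])
        assert metrics.recall >= 0.95
        assert metrics.precision >= 0.95
        assert metrics.max_boundary_error <= 21
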