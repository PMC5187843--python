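"""Sliding-window detection of PHAS loci.

The method enumerates maximal read-covered regions, slides a 210-nt window
(10 phase lengths) in 21-nt steps across each, and for every window and
every phase register x in [1, 21] asks whether occupied 21-nt read start
positions concentrate on register x more than chance allows.  Chance is
the hypergeometric draw: of the N candidate start positions in the window
(both strands), m lie on register x; if n positions are occupied by at
least one 21-nt species, the upper-tail probability of observing k or more
occupied on-phase positions is the window's p-value for that register.
Windows below the significance threshold are merged along a common phase
track into candidate loci, scored with a log-scale phase score rewarding
on-phase abundance across many occupied cycles, ranked, and capped at the
top K.

Antisense reads of a DCL-processed duplex sit 2 nt to the left of their
sense partner (the 2-nt 3' overhang), so minus-strand on-phase starts are
displaced by the duplex offset.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom

from .read_model import CollapsedReadSet, pool_samples
from .sam_io import GenomicInterval

logger = logging.getLogger("phaswindow")


@dataclass(frozen=True)
class ScanParams:
    """Sliding-window scan parameters.

    W: window width in nt (10 phase lengths). s: the phase length and the
    window step. p_threshold: significance cutoff on the raw hypergeometric
    p-value (no multiple-testing correction; the method couples a stringent
    threshold with top-K selection). top_k: number of ranked candidates
    retained. duplex_offset: displacement of antisense phased starts.
    """

    W: int = 210
    s: int = 21
    p_threshold: float = 1e-6
    top_k: int = 50
    duplex_offset: int = 2

    def __post_init__(self) -> None:
        if self.W <= 0 or self.s <= 0 or self.W % self.s != 0:
            raise ValueError("W must be a positive multiple of s")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def cycles(self) -> int:
        """Phase cycles per window (W/s)."""
        return self.W // self.s


@dataclass(frozen=True)
class PhaseWindow:
    interval: GenomicInterval
    register: int  # x in [1, s]


@dataclass(frozen=True)
class PhaseTest:
    """The hypergeometric quadruple for one (window, register) test.

    N: candidate start positions in the window, both strands.
    m: on-phase candidates for the tested register.
    n: occupied candidates (>= 1 read of the phase length).
    k: occupied on-phase candidates.
    """

    N: int
    m: int
    n: int
    k: int
    p_value: float


@dataclass(frozen=True)
class ScanHit:
    window: PhaseWindow
    test: PhaseTest


@dataclass(frozen=True)
class PhasRegion:
    """A called PHAS locus.

    phase0 is the absolute plus-strand phase residue (start mod s) of the
    locus's phase track; register is the same track expressed relative to
    the region start (x in [1, s]).
    """

    interval: GenomicInterval
    phase0: int
    register: int
    p_value: float
    phase_score: float
    rank: int
    n_windows: int
    k: int


# ---------------------------------------------------------------------------
# Covered regions and window enumeration

def build_covered_regions(reads: CollapsedReadSet) -> List[GenomicInterval]:
    """Union of read intervals: overlapping or bookended reads merge into
    maximal covered regions, sorted by (chrom, start)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for r in reads:
        by_chrom[r.chrom].append((r.start, r.end))
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s0, e0 in ivs[1:]:
            if s0 <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, e0)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s0, e0
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def enumerate_windows(region: GenomicInterval,
                      params: ScanParams = ScanParams()) -> List[GenomicInterval]:
    """Window anchors over one covered region: starts at region.start + s*j
    for j = 0 .. ceil(len/s) - 1, each of width W.  The last window may
    extend past the region's 3' end so trailing reads are always tested;
    when region lengths are multiples of s the total window count over all
    regions equals covered length / s exactly."""
    n_win = -(-len(region) // params.s)  # ceil
    return [GenomicInterval(region.chrom,
                            region.start + params.s * j,
                            region.start + params.s * j + params.W)
            for j in range(n_win)]


def on_phase_positions(window: PhaseWindow,
                       params: ScanParams = ScanParams()
                       ) -> Tuple[List[int], List[int]]:
    """Candidate on-phase start positions for a window and register.

    Plus-strand starts satisfy p = (window.start + x - 1) mod s; antisense
    starts are displaced left by the duplex offset.  Candidates are all
    starts inside the window, so each strand contributes exactly W/s
    positions.
    """
    w = window.interval.start
    s = params.s
    x = window.register
    if not (1 <= x <= s):
        raise ValueError(f"register must lie in [1, {s}], got {x}")
    plus0 = w + ((x - 1) % s)
    minus0 = w + ((x - 1 - params.duplex_offset) % s)
    plus = [plus0 + s * j for j in range(params.cycles)]
    minus = [minus0 + s * j for j in range(params.cycles)]
    return plus, minus


# ---------------------------------------------------------------------------
# The hypergeometric phase test

def phasing_pvalue(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k): the chance that at
    least k of n occupied positions (drawn without replacement from N
    candidates, m of them on-phase) fall on-phase.  Computed in log space
    by scipy's survival function, stable for N up to 1e4."""
    if not (0 <= k <= min(n, m) and 0 <= n <= N and 0 <= m <= N):
        raise ValueError(f"invalid hypergeometric quadruple "
                         f"N={N}, m={m}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def phase_score(P: float, U: float, k: int) -> float:
    """Phase score ln[(1 + 10*P/(1 + U))^(k-2)] for k occupied on-phase
    positions with summed on-phase abundance P and out-of-phase abundance
    U.  Zero for k <= 2; strictly increasing in P and k, decreasing in U."""
    if P < 0 or U < 0:
        raise ValueError("abundances must be nonnegative")
    exponent = max(k - 2, 0)
    return exponent * math.log1p(10.0 * P / (1.0 + U))


# ---------------------------------------------------------------------------
# Occupancy index

class Occupancy:
    """Per-chromosome sorted arrays of occupied phase-length start
    positions and their pooled abundances, one pair per strand."""

    def __init__(self, reads: CollapsedReadSet, phasing_len: int = 21):
        pooled = pool_samples(reads)
        acc: Dict[Tuple[str, str], Dict[int, int]] = defaultdict(dict)
        for r in pooled:
            if r.length != phasing_len:
                continue
            d = acc[(r.chrom, r.strand)]
            d[r.start] = d.get(r.start, 0) + r.count
        self.starts: Dict[Tuple[str, str], np.ndarray] = {}
        self.counts: Dict[Tuple[str, str], np.ndarray] = {}
        for key, d in acc.items():
            pos = np.array(sorted(d), dtype=np.int64)
            self.starts[key] = pos
            self.counts[key] = np.array([d[p] for p in pos], dtype=np.int64)

    def in_range(self, chrom: str, strand: str, start: int, end: int
                 ) -> Tuple[np.ndarray, np.ndarray]:
        """Occupied starts (and abundances) with start in [start, end)."""
        key = (chrom, strand)
        if key not in self.starts:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        pos = self.starts[key]
        lo, hi = np.searchsorted(pos, (start, end))
        return pos[lo:hi], self.counts[key][lo:hi]


def scan(reads: CollapsedReadSet,
         params: ScanParams = ScanParams()) -> List[ScanHit]:
    """Run the sliding-window phase test over all covered regions.

    For every window and every register x in [1, s], builds the
    hypergeometric quadruple from pooled 21-nt read-start occupancy and
    returns the (window, register) pairs with p below the threshold.  The
    result depends only on the read multiset, not its order.
    """
    occ = Occupancy(reads, phasing_len=params.s)
    regions = build_covered_regions(reads)
    s = params.s
    N = 2 * params.W
    m = 2 * params.cycles

    # gather quadruples first, batch the p-value evaluation
    pend: List[Tuple[GenomicInterval, int, int, int]] = []  # (win, x, n, k)
    windows_per_chrom: Dict[str, int] = defaultdict(int)
    for region in regions:
        for win in enumerate_windows(region, params):
            windows_per_chrom[region.chrom] += 1
            pp, pc = occ.in_range(win.chrom, "+", win.start, win.end)
            mp, mc = occ.in_range(win.chrom, "-", win.start, win.end)
            n = len(pp) + len(mp)
            if n == 0:
                continue
            k_by_x = np.zeros(s, dtype=np.int64)
            if len(pp):
                xs = (pp - win.start) % s  # register index x-1
                np.add.at(k_by_x, xs, 1)
            if len(mp):
                xs = (mp - win.start + params.duplex_offset) % s
                np.add.at(k_by_x, xs, 1)
            for xi in range(s):
                k = int(k_by_x[xi])
                if k >= 1:  # k = 0 has p = 1.0 and can never pass
                    pend.append((win, xi + 1, n, k))
    for chrom, cnt in sorted(windows_per_chrom.items()):
        logger.info("scan: %s: %d windows examined", chrom, cnt)

    if not pend:
        return []
    ns = np.array([t[2] for t in pend])
    ks = np.array([t[3] for t in pend])
    pvals = hypergeom.sf(ks - 1, N, m, ns)
    hits: List[ScanHit] = []
    for (win, x, n, k), p in zip(pend, pvals):
        if p < params.p_threshold:
            hits.append(ScanHit(
                PhaseWindow(win, x),
                PhaseTest(N=N, m=m, n=n, k=k, p_value=float(p))))
    return hits


# ---------------------------------------------------------------------------
# Region calling

def _region_stats(occ: Occupancy, chrom: str, lo: int, hi: int, phase0: int,
                  params: ScanParams) -> Tuple[int, int, int, float, float]:
    """Trim [lo, hi) to the outermost on-phase occupied starts and compute
    (start, end, k, P, U) over the trimmed extent."""
    s = params.s
    pp, pc = occ.in_range(chrom, "+", lo, hi)
    mp, mc = occ.in_range(chrom, "-", lo, hi)
    on_plus = (pp % s) == phase0
    on_minus = (mp % s) == (phase0 - params.duplex_offset) % s
    on_starts = np.concatenate([pp[on_plus], mp[on_minus]])
    if len(on_starts) == 0:
        return (lo, hi, 0, 0.0, float(np.sum(pc) + np.sum(mc)))
    start = int(on_starts.min())
    end = int(on_starts.max()) + s
    # abundances over the trimmed extent
    pp, pc = occ.in_range(chrom, "+", start, end)
    mp, mc = occ.in_range(chrom, "-", start, end)
    on_plus = (pp % s) == phase0
    on_minus = (mp % s) == (phase0 - params.duplex_offset) % s
    P = float(np.sum(pc[on_plus]) + np.sum(mc[on_minus]))
    U = float(np.sum(pc[~on_plus]) + np.sum(mc[~on_minus]))
    k = int(np.sum(on_plus) + np.sum(on_minus))
    return (start, end, k, P, U)


def call_regions(hits: Sequence[ScanHit], reads: CollapsedReadSet,
                 params: ScanParams = ScanParams()) -> List[PhasRegion]:
    """Merge significant windows sharing a phase track into loci, score,
    rank, and retain the top K.

    Windows on one chromosome belong to the same phase track when their
    plus-strand on-phase starts share the absolute residue (window.start +
    x - 1) mod s; overlapping or bookended windows on a track merge.
    Region boundaries are trimmed to the outermost on-phase occupied
    positions (+s on the right); each region carries its minimum window
    p-value and a phase score over the merged extent.  Ranking is by score
    descending, ties by smaller p-value then leftmost coordinate.
    """
    occ = Occupancy(reads, phasing_len=params.s)
    s = params.s
    tracks: Dict[Tuple[str, int], List[ScanHit]] = defaultdict(list)
    for h in hits:
        phase0 = (h.window.interval.start + h.window.register - 1) % s
        tracks[(h.window.interval.chrom, phase0)].append(h)

    called: List[PhasRegion] = []
    for (chrom, phase0), track in tracks.items():
        track.sort(key=lambda h: h.window.interval.start)
        cluster: List[ScanHit] = []
        clusters: List[List[ScanHit]] = []
        cur_end = -1
        for h in track:
            iv = h.window.interval
            if not cluster or iv.start <= cur_end:
                cluster.append(h)
                cur_end = max(cur_end, iv.end)
            else:
                clusters.append(cluster)
                cluster, cur_end = [h], iv.end
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            lo = min(h.window.interval.start for h in cl)
            hi = max(h.window.interval.end for h in cl)
            start, end, k, P, U = _region_stats(occ, chrom, lo, hi,
                                                phase0, params)
            if k == 0:
                continue
            best_p = min(h.test.p_value for h in cl)
            score = phase_score(P, U, k)
            register = (phase0 - start) % s + 1
            called.append(PhasRegion(
                interval=GenomicInterval(chrom, start, end),
                phase0=phase0, register=register, p_value=best_p,
                phase_score=score, rank=0, n_windows=len(cl), k=k))

    called.sort(key=lambda r: (-r.phase_score, r.p_value,
                               r.interval.chrom, r.interval.start))
    ranked = [PhasRegion(r.interval, r.phase0, r.register, r.p_value,
                         r.phase_score, i + 1, r.n_windows, r.k)
              for i, r in enumerate(called[:params.top_k])]
    return ranked
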