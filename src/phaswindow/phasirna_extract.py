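"""Individual phasiRNA species within called loci.

A called locus fixes a phase track; the 21-nt species whose starts lie on
that track (antisense species displaced by the duplex offset) are the
locus's phasiRNAs.  Two filters follow: an abundance filter retaining
species whose pooled count across samples exceeds a threshold (>3000 over
seven samples at full scale; scaled proportionally for runs with fewer
samples), and a locus-level phase-profile filter discarding loci whose
21-nt abundance spreads over more than two dominant registers — the
programmatic form of judging a phase graph by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .phas_scan import PhasRegion, ScanParams
from .read_model import CollapsedReadSet
from .sam_io import MappedRead

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PhasiRNA:
    """One on-phase 21-nt species of a locus, with per-sample counts."""

    locus_id: str
    chrom: str
    start: int
    strand: str
    sequence: Optional[str]
    sample_counts: Dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.sample_counts.values())


@dataclass
class PhaseProfile:
    """Abundance of 21-nt reads per phase register (1..s) of a locus,
    minus-strand reads projected onto the plus strand by +duplex_offset
    before register assignment."""

    locus_id: str
    abundance: np.ndarray  # length s

    @property
    def total(self) -> float:
        return float(self.abundance.sum())

    def dominant_registers(self, min_bin_fraction: float = 0.10) -> List[int]:
        if self.total == 0:
            return []
        cut = min_bin_fraction * self.total
        return [int(r) + 1 for r in np.nonzero(self.abundance > cut)[0]]


def scaled_min_total(min_total: int, n_samples: int,
                     reference_samples: int = 7) -> float:
    """The full-scale abundance threshold refers to a pooled count over
    seven libraries; with a different sample count the threshold scales
    proportionally."""
    return min_total * (n_samples / reference_samples)


def _locus_species(region: PhasRegion, reads: CollapsedReadSet,
                   params: ScanParams) -> Dict[Tuple[int, str], Dict[str, int]]:
    """21-nt species in the locus keyed by (start, strand), with
    per-sample counts merged across input records.  Minus-strand species
    may start up to duplex_offset nt left of the region (the antisense
    partner of the first duplex)."""
    s = params.s
    out: Dict[Tuple[int, str], Dict[str, int]] = {}
    for r in reads:
        lo = region.interval.start - (params.duplex_offset
                                      if r.strand == "-" else 0)
        if (r.chrom != region.interval.chrom or r.length != s
                or not (lo <= r.start < region.interval.end)):
            continue
        d = out.setdefault((r.start, r.strand), {})
        d[r.sample] = d.get(r.sample, 0) + r.count
    return out


def extract_phasirnas(region: PhasRegion, reads: CollapsedReadSet,
                      min_total: float = 3000,
                      params: ScanParams = ScanParams(),
                      genome: Optional[Dict[str, str]] = None,
                      locus_id: Optional[str] = None) -> List[PhasiRNA]:
    """On-phase species of one locus with pooled count strictly greater
    than ``min_total``, sorted by coordinate.

    Species sequences are taken from the genome when provided
    (reverse-complemented for minus-strand species); otherwise the
    coordinates alone identify the species.
    """
    s = params.s
    lid = locus_id or (f"{region.interval.chrom}_"
                       f"{region.interval.start}_{region.interval.end}")
    minus_phase = (region.phase0 - params.duplex_offset) % s
    out: List[PhasiRNA] = []
    for (start, strand), per_sample in _locus_species(region, reads, params).items():
        phase = region.phase0 if strand == "+" else minus_phase
        if start % s != phase:
            continue
        if sum(per_sample.values()) <= min_total:
            continue
        seq = None
        if genome is not None:
            raw = genome[region.interval.chrom][start:start + s]
            seq = raw if strand == "+" else _revcomp(raw)
        out.append(PhasiRNA(lid, region.interval.chrom, start, strand,
                            seq, dict(per_sample)))
    out.sort(key=lambda p: (p.start, p.strand))
    return out


def phase_profile(region: PhasRegion, reads: CollapsedReadSet,
                  params: ScanParams = ScanParams()) -> PhaseProfile:
    """Histogram of 21-nt read abundance over the s registers of a locus.

    Register r of a species is its plus-strand-projected start offset from
    the region start, modulo s (1-based); projection adds the duplex
    offset to minus-strand starts so a perfect duplex ladder collapses to
    a single register.
    """
    s = params.s
    lid = (f"{region.interval.chrom}_"
           f"{region.interval.start}_{region.interval.end}")
    abundance = np.zeros(s, dtype=float)
    for (start, strand), per_sample in _locus_species(region, reads, params).items():
        proj = start if strand == "+" else start + params.duplex_offset
        r = (proj - region.interval.start) % s
        abundance[r] += sum(per_sample.values())
    return PhaseProfile(lid, abundance)


@dataclass(frozen=True)
class PhaseCountDecision:
    locus_id: str
    kept: bool
    dominant_registers: Tuple[int, ...]
    reason: str


def filter_by_phase_count(profiles: Sequence[PhaseProfile],
                          max_phases: int = 2,
                          min_bin_fraction: float = 0.10
                          ) -> Tuple[List[str], List[PhaseCountDecision]]:
    """Discard loci whose profile has more than ``max_phases`` dominant
    registers (a register is dominant when it carries more than
    ``min_bin_fraction`` of the locus's 21-nt abundance).  Returns the
    retained locus ids and the full decision list including discards."""
    kept: List[str] = []
    decisions: List[PhaseCountDecision] = []
    for prof in profiles:
        if prof.total == 0:
            decisions.append(PhaseCountDecision(prof.locus_id, False, (), "empty"))
            continue
        dom = tuple(prof.dominant_registers(min_bin_fraction))
        if len(dom) > max_phases:
            decisions.append(PhaseCountDecision(
                prof.locus_id, False, dom,
                f"{len(dom)} dominant registers > {max_phases}"))
        else:
            kept.append(prof.locus_id)
            decisions.append(PhaseCountDecision(prof.locus_id, True, dom, "ok"))
    return kept, decisions
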