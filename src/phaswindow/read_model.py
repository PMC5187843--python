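"""Collapse raw alignments into unique read species and apply the
retention filters that precede the phasing scan.

Two filters gate the scan: the library-level 18–30 nt length window, and
the phasing-specific rule that only species mapping to at most six genomic
positions — and of the tested phase length (21 nt) — are fed to the
sliding-window test.  Multi-mapped species contribute their full count at
every retained alignment during discovery, but are tabulated once (a
single alignment per read) for expression, mirroring the two mapping modes
of the upstream aligner configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Tuple

from .sam_io import MappedRead

SpeciesKey = Tuple[str, int, str, int, str]  # (chrom, start, strand, length, sample)


@dataclass(frozen=True)
class ReadFilterParams:
    """Retention thresholds applied before phasing.

    min_len/max_len bound the library (18–30 nt inclusive); phasing_len is
    the phase length under test (21 nt); max_hits_phasing caps genomic
    multiplicity for the scan (6); max_hits_discovery is the aligner-side
    cap on reported alignments (20).
    """

    min_len: int = 18
    max_len: int = 30
    phasing_len: int = 21
    max_hits_phasing: int = 6
    max_hits_discovery: int = 20

    def __post_init__(self) -> None:
        if not (self.min_len <= self.phasing_len <= self.max_len):
            raise ValueError("require min_len <= phasing_len <= max_len")
        if self.max_hits_phasing < 1:
            raise ValueError("max_hits_phasing must be >= 1")


@dataclass
class CollapsedReadSet:
    """Unique read species keyed by (chrom, start, strand, length, sample)."""

    reads: Dict[SpeciesKey, MappedRead] = field(default_factory=dict)

    @property
    def total_mapped(self) -> int:
        return sum(r.count for r in self.reads.values())

    @property
    def length_histogram(self) -> Counter:
        h: Counter = Counter()
        for r in self.reads.values():
            h[r.length] += r.count
        return h

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({r.sample for r in self.reads.values()}))

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads.values())


def species_key(read: MappedRead) -> SpeciesKey:
    return (read.chrom, read.start, read.strand, read.length, read.sample)


def collapse(alignments: Iterable[MappedRead]) -> CollapsedReadSet:
    """Merge identical (chrom, start, strand, length, sample) alignments,
    summing counts.  Total mapped count is conserved."""
    out: Dict[SpeciesKey, MappedRead] = {}
    for aln in alignments:
        key = species_key(aln)
        prev = out.get(key)
        if prev is None:
            out[key] = aln
        else:
            out[key] = replace(prev, count=prev.count + aln.count,
                               n_hits=max(prev.n_hits, aln.n_hits))
    return CollapsedReadSet(out)


def filter_length(read_set: CollapsedReadSet,
                  params: ReadFilterParams = ReadFilterParams()) -> CollapsedReadSet:
    """Retain species with min_len <= length <= max_len (bounds inclusive)."""
    return CollapsedReadSet({
        k: r for k, r in read_set.reads.items()
        if params.min_len <= r.length <= params.max_len
    })


def filter_for_phasing(read_set: CollapsedReadSet,
                       params: ReadFilterParams = ReadFilterParams()
                       ) -> CollapsedReadSet:
    """Retain only species eligible for the phasing scan: mapped to no more
    than ``max_hits_phasing`` genomic positions and exactly ``phasing_len``
    nt long.  Other species remain available for expression tabulation."""
    return CollapsedReadSet({
        k: r for k, r in read_set.reads.items()
        if r.n_hits <= params.max_hits_phasing and r.length == params.phasing_len
    })


def pool_samples(read_set: CollapsedReadSet) -> CollapsedReadSet:
    """Sum counts across samples for the phasing scan; per-sample
    resolution is kept elsewhere for phasiRNA tables."""
    pooled: Dict[SpeciesKey, MappedRead] = {}
    for r in read_set:
        key = (r.chrom, r.start, r.strand, r.length, "pooled")
        prev = pooled.get(key)
        if prev is None:
            pooled[key] = replace(r, sample="pooled")
        else:
            pooled[key] = replace(prev, count=prev.count + r.count,
                                  n_hits=max(prev.n_hits, r.n_hits))
    return CollapsedReadSet(pooled)
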