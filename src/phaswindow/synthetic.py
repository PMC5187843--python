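"""Seeded simulator of phased small-RNA libraries with ground truth.

The generator emulates the structure of a mapped plant sRNA-seq library:
a random genome, planted PHAS loci emitting duplex 21-nt read ladders
(antisense starts displaced 2 nt left by the Dicer 3' overhang), a
planted miRNA trigger whose perfect-complement binding site cleaves at a
phase-registered position within 420 nt of the first phasiRNA, and a
uniform background of 18–30-nt reads over the genome.  Background 21-mers
that would land exactly on a planted register inside a locus are
resampled so truth labels stay unambiguous.  Read sequences are taken
verbatim from the genome (no sequencing error), matching a zero-mismatch
mapping regime.  Per-species counts are negative-binomially distributed
(clipped to >= 1 so every planted species is observed); a subset of
species per locus is highly abundant so the pooled-count phasiRNA filter
has both survivors and casualties.  All randomness flows from the config
seed; identical configs yield byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .phasirna_extract import PhasiRNA, _revcomp
from .sam_io import (GenomicInterval, MappedRead, write_alignments_sam,
                     write_alignments_table, write_fasta, write_regions)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    Depth parameters are per species per sample; ``background_rate`` is
    background species per kb per sample.  ``locus_length`` must be a
    multiple of the phase length (21).
    """

    genome_length: int = 200_000
    n_chroms: int = 2
    n_loci: int = 20
    locus_length: int = 420
    min_phased_positions: int = 10
    max_phased_positions: int = 20
    depth_mean: float = 40.0
    depth_dispersion: float = 10.0
    abundant_per_locus: int = 3
    abundant_mean: float = 800.0
    duplex_offset: int = 2
    background_rate: float = 5.0
    background_min_len: int = 18
    background_max_len: int = 30
    n_samples: int = 2
    n_mirnas: int = 3
    trigger_mirna_len: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus_length % 21 != 0 or self.locus_length < 42:
            raise ValueError("locus_length must be a multiple of 21, >= 42")
        cycles = self.locus_length // 21
        if not (1 <= self.min_phased_positions
                <= self.max_phased_positions <= cycles):
            raise ValueError("phased_positions range exceeds locus cycles")


@dataclass(frozen=True)
class TruthLocus:
    interval: GenomicInterval
    phase0: int  # plus-strand start residue mod 21
    mirna_id: str
    cleavage: int
    trigger_distance: int


@dataclass
class GroundTruth:
    loci: List[TruthLocus]
    phasirnas: List[PhasiRNA]  # every planted on-phase species, with counts
    mirnas: Dict[str, str]  # id -> RNA sequence 5'->3'

    def abundant_phasirnas(self, min_total: float) -> List[PhasiRNA]:
        return [p for p in self.phasirnas if p.total_count > min_total]


@dataclass
class SimResult:
    config: SimConfig
    genome: Dict[str, str]
    reads: List[MappedRead]
    truth: GroundTruth

    @property
    def samples(self) -> List[str]:
        return [f"sample{i + 1}" for i in range(self.config.n_samples)]


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    """Negative binomial with given mean and size (dispersion) parameter,
    clipped to >= 1."""
    p = dispersion / (dispersion + mean)
    draws = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(draws, 1)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def simulate(config: SimConfig) -> SimResult:
    """Generate genome, reads, and ground truth for one run."""
    rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chroms
    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chroms)]
    genome_arr = {c: _BASES[rng.integers(0, 4, size=chrom_len)].copy()
                  for c in chrom_names}
    samples = [f"sample{i + 1}" for i in range(config.n_samples)]

    # --- place non-overlapping loci with room for the upstream trigger site
    margin = 600
    per_chrom = [config.n_loci // config.n_chroms
                 + (1 if i < config.n_loci % config.n_chroms else 0)
                 for i in range(config.n_chroms)]
    locus_pos: List[Tuple[str, int]] = []
    for chrom, n_here in zip(chrom_names, per_chrom):
        if n_here == 0:
            continue
        need = n_here * (config.locus_length + margin) + margin
        if need > chrom_len:
            raise ValueError(f"cannot pack {n_here} loci of "
                             f"{config.locus_length} nt into {chrom_len} nt")
        slack = chrom_len - need
        gaps = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1))
        pos = margin + gaps[0]
        for g in gaps[1:]:
            locus_pos.append((chrom, int(pos)))
            pos += config.locus_length + margin + g

    # --- trigger miRNAs, round-robin over loci
    mirnas = {f"sim-miR{i + 1}": _random_rna(rng, config.trigger_mirna_len)
              for i in range(max(config.n_mirnas, 1) if config.n_loci else 0)}
    mirna_ids = list(mirnas)

    loci: List[TruthLocus] = []
    phasirnas: List[PhasiRNA] = []
    reads: List[MappedRead] = []
    cycles = config.locus_length // 21

    for li, (chrom, start) in enumerate(locus_pos):
        phase0 = start % 21
        mid = mirna_ids[li % len(mirna_ids)]
        L = len(mirnas[mid])
        # plant the binding site: cleavage on-register, <= 420 nt upstream
        dist = 21 * int(rng.integers(0, 3))
        cleavage = start - dist
        site_start = cleavage - L + 10
        site_dna = _revcomp(mirnas[mid].replace("U", "T"))
        genome_arr[chrom][site_start:site_start + L] = list(site_dna)

        # occupied duplex cycles; cycle 0 always occupied (anchors trigger)
        n_pos = int(rng.integers(config.min_phased_positions,
                                 config.max_phased_positions + 1))
        others = rng.permutation(np.arange(1, cycles))[:n_pos - 1]
        occupied = sorted([0] + [int(j) for j in others])
        # the truth interval spans the planted ladder, not empty tail cycles
        interval = GenomicInterval(chrom, start,
                                   start + 21 * (occupied[-1] + 1))
        loci.append(TruthLocus(interval, phase0, mid, cleavage, dist))
        abundant = set(int(j) for j in
                       rng.permutation(occupied)[:config.abundant_per_locus])
        lid = f"{chrom}_{interval.start}_{interval.end}"
        for j in occupied:
            p_plus = start + 21 * j
            p_minus = p_plus - config.duplex_offset
            for (pos, strand) in ((p_plus, "+"), (p_minus, "-")):
                mean = config.abundant_mean if (j in abundant and strand == "+") \
                    else config.depth_mean
                counts = _nb_counts(rng, mean, config.depth_dispersion,
                                    config.n_samples)
                per_sample = {s: int(c) for s, c in zip(samples, counts)}
                phasirnas.append(PhasiRNA(lid, chrom, pos, strand, None,
                                          per_sample))
                for s in samples:
                    reads.append(MappedRead(chrom, pos, 21, strand,
                                            sample=s,
                                            count=per_sample[s], n_hits=1))

    # --- background reads, after loci so rejection sees the truth registers
    def on_planted_register(chrom: str, pos: int, strand: str) -> bool:
        for t in loci:
            if t.interval.chrom != chrom:
                continue
            lo = t.interval.start - config.duplex_offset
            if lo <= pos < t.interval.end:
                want = t.phase0 if strand == "+" else \
                    (t.phase0 - config.duplex_offset) % 21
                if pos % 21 == want:
                    return True
        return False

    n_bg = rng.poisson(config.background_rate * chrom_len / 1000.0,
                       size=(config.n_chroms, config.n_samples))
    for ci, chrom in enumerate(chrom_names):
        for si, s in enumerate(samples):
            for _ in range(int(n_bg[ci, si])):
                for _attempt in range(100):
                    length = int(rng.integers(config.background_min_len,
                                              config.background_max_len + 1))
                    pos = int(rng.integers(0, chrom_len - length))
                    strand = "+" if rng.random() < 0.5 else "-"
                    if length == 21 and on_planted_register(chrom, pos, strand):
                        continue  # resample: keep truth labels clean
                    break
                count = int(_nb_counts(rng, 2.0, 5.0, 1)[0])
                reads.append(MappedRead(chrom, pos, length, strand,
                                        sample=s, count=count, n_hits=1))

    # attach genome-forward sequences
    genome = {c: "".join(arr) for c, arr in genome_arr.items()}
    reads = [MappedRead(r.chrom, r.start, r.length, r.strand,
                        sequence=genome[r.chrom][r.start:r.start + r.length],
                        sample=r.sample, count=r.count, n_hits=r.n_hits)
             for r in reads]
    phasirnas.sort(key=lambda p: (p.chrom, p.start, p.strand))
    reads.sort(key=lambda r: (r.chrom, r.start, r.strand, r.length, r.sample))
    return SimResult(config, genome, reads,
                     GroundTruth(loci, phasirnas, mirnas))


def write_outputs(result: SimResult, out_dir: str | Path) -> Dict[str, Path]:
    """Write genome.fa, reads.sam, reads.tsv, mirnas.fa and the truth
    files; deterministic byte-for-byte given the same config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "genome": "genome.fa", "reads_sam": "reads.sam",
        "reads_tsv": "reads.tsv", "mirnas": "mirnas.fa",
        "truth_loci": "truth_loci.bed",
        "truth_phasirnas": "truth_phasirnas.tsv",
        "truth_triggers": "truth_triggers.tsv"}.items()}
    write_fasta(result.genome, paths["genome"])
    chrom_lengths = {c: len(s) for c, s in result.genome.items()}
    write_alignments_sam(result.reads, paths["reads_sam"], chrom_lengths)
    write_alignments_table(result.reads, paths["reads_tsv"])
    write_fasta(result.truth.mirnas, paths["mirnas"])
    write_regions([t.interval for t in result.truth.loci], paths["truth_loci"],
                  format="bed",
                  attributes=[{"name": f"locus_{i + 1}", "phase_score": 0.0}
                              for i in range(len(result.truth.loci))])
    samples = result.samples
    with open(paths["truth_phasirnas"], "w") as fh:
        fh.write("locus\tchrom\tstart\tstrand\t"
                 + "\t".join(samples) + "\ttotal\n")
        for p in result.truth.phasirnas:
            row = [p.locus_id, p.chrom, str(p.start), p.strand]
            row += [str(p.sample_counts.get(s, 0)) for s in samples]
            row.append(str(p.total_count))
            fh.write("\t".join(row) + "\n")
    with open(paths["truth_triggers"], "w") as fh:
        fh.write("mirna\tchrom\tlocus_start\tlocus_end\tcleavage\tdistance\n")
        for t in result.truth.loci:
            fh.write(f"{t.mirna_id}\t{t.interval.chrom}\t{t.interval.start}\t"
                     f"{t.interval.end}\t{t.cleavage}\t{t.trigger_distance}\n")
    return paths


# ---------------------------------------------------------------------------
# Truth comparison

@dataclass
class ComparisonMetrics:
    precision: float
    recall: float
    n_called: int
    n_truth: int
    n_matched: int
    boundary_errors: List[int] = field(default_factory=list)

    @property
    def max_boundary_error(self) -> int:
        return max(self.boundary_errors, default=0)


def compare_regions(called: Sequence[GenomicInterval],
                    truth: Sequence[GenomicInterval],
                    min_reciprocal: float = 0.5) -> ComparisonMetrics:
    """Match called and truth intervals by reciprocal overlap >= 0.5 (of
    the longer interval); boundary error is the larger of the start and
    end discrepancies of each matched pair."""
    matched_truth: set = set()
    matched_called: set = set()
    boundary: List[int] = []
    for ci, c in enumerate(called):
        best, best_ov = None, min_reciprocal
        for ti, t in enumerate(truth):
            if ti in matched_truth:
                continue
            ov = c.reciprocal_overlap(t)
            if ov >= best_ov:
                best, best_ov = ti, ov
        if best is not None:
            matched_truth.add(best)
            matched_called.add(ci)
            t = truth[best]
            boundary.append(max(abs(c.start - t.start), abs(c.end - t.end)))
    n_m = len(matched_called)
    return ComparisonMetrics(
        precision=n_m / len(called) if called else 1.0,
        recall=n_m / len(truth) if truth else 1.0,
        n_called=len(called), n_truth=len(truth), n_matched=n_m,
        boundary_errors=boundary)


def compare_exact(called: Sequence[Tuple[str, int, str]],
                  truth: Sequence[Tuple[str, int, str]]) -> ComparisonMetrics:
    """Precision/recall on exact (chrom, start, strand) coordinates."""
    cs, ts = set(called), set(truth)
    inter = cs & ts
    return ComparisonMetrics(
        precision=len(inter) / len(cs) if cs else 1.0,
        recall=len(inter) / len(ts) if ts else 1.0,
        n_called=len(cs), n_truth=len(ts), n_matched=len(inter))
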