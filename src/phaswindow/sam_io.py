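"""Readers and writers for the formats the tool touches.

Mapped small-RNA reads come in as SAM/BAM (via pysam) or as a collapsed
tab-separated dialect; called loci go out as BED6 or GFF3; genomes and
mature miRNAs are FASTA.  Internal coordinates are uniformly 0-based
half-open; conversion to the 1-based conventions of SAM and GFF3 happens
only at the format boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("phaswindow")

TABLE_COLUMNS = ("chrom", "start", "strand", "length", "sequence",
                 "sample", "count", "n_hits")

_COLLAPSED_NAME = re.compile(r"_x(\d+)$")


@dataclass(frozen=True)
class MappedRead:
    """One collapsed alignment of a small-RNA species.

    ``start`` is the 0-based leftmost genomic coordinate; the read occupies
    the half-open interval ``[start, start + length)``.  ``count`` is the
    number of copies of this exact species observed in ``sample`` and
    ``n_hits`` the number of valid genomic alignments of the sequence.
    ``sequence`` is stored in genome-forward orientation (as in SAM).
    """

    chrom: str
    start: int
    length: int
    strand: str
    sequence: Optional[str] = None
    sample: str = "sample1"
    count: int = 1
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.n_hits < 1:
            raise ValueError(f"n_hits must be >= 1, got {self.n_hits}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match read length")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Overlap fraction relative to the longer of the two intervals."""
        if self.chrom != other.chrom:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        return inter / max(len(self), len(other))


class FormatError(ValueError):
    """Raised on a malformed record or an unknown format name."""


def _count_from_name(name: Optional[str]) -> int:
    """Collapsed-FASTA style names encode abundance as ``id_xCOUNT``."""
    if not name:
        return 1
    m = _COLLAPSED_NAME.search(name)
    return int(m.group(1)) if m else 1


def _is_ungapped(segment: pysam.AlignedSegment) -> bool:
    # phasing assumes perfect, ungapped matches: a single M/=/X op only
    cig = segment.cigartuples
    return cig is not None and len(cig) == 1 and cig[0][0] in (0, 7, 8)


def read_alignments(path: str | Path, format: str = "sam",
                    sample: Optional[str] = None) -> Iterator[MappedRead]:
    """Stream :class:`MappedRead` records from a SAM/BAM file or the
    collapsed tabular dialect.

    SAM flag bit 0x10 maps to strand '-'; unmapped records are skipped;
    records whose CIGAR contains indels or clips are rejected (the phasing
    model assumes perfect ungapped matches) and counted in the log.  The NH
    tag populates ``n_hits`` (default 1), the RG tag or ``sample`` argument
    populates ``sample``, and read names of the form ``id_xCOUNT`` populate
    ``count``.
    """
    path = str(path)
    if format in ("sam", "bam"):
        yield from _read_sam(path, format, sample)
    elif format == "table":
        yield from _read_table(path)
    else:
        raise FormatError(f"unknown alignment format: {format!r}")


def _read_sam(path: str, format: str, sample: Optional[str]) -> Iterator[MappedRead]:
    mode = "rb" if format == "bam" else "r"
    n_rejected = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for i, seg in enumerate(fh):
            if seg.is_unmapped:
                continue
            if not _is_ungapped(seg):
                n_rejected += 1
                continue
            try:
                strand = "-" if seg.is_reverse else "+"
                n_hits = seg.get_tag("NH") if seg.has_tag("NH") else 1
                if seg.has_tag("RG"):
                    smp = str(seg.get_tag("RG"))
                else:
                    smp = sample or "sample1"
                yield MappedRead(
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    length=seg.query_length or seg.infer_query_length(),
                    strand=strand,
                    sequence=seg.query_sequence,
                    sample=smp,
                    count=_count_from_name(seg.query_name),
                    n_hits=int(n_hits),
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"malformed record {i} in {path}: {exc}") from exc
    if n_rejected:
        logger.info("%s: rejected %d gapped/clipped alignments", path, n_rejected)


def _read_table(path: str) -> Iterator[MappedRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABLE_COLUMNS:
            raise FormatError(f"unexpected table header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(TABLE_COLUMNS)} fields, got {len(fields)}")
            try:
                chrom, start, strand, length, seq, smp, count, n_hits = fields
                yield MappedRead(
                    chrom=chrom, start=int(start), strand=strand,
                    length=int(length),
                    sequence=seq if seq not in (".", "") else None,
                    sample=smp, count=int(count), n_hits=int(n_hits),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_alignments_table(reads: Iterable[MappedRead], path: str | Path) -> None:
    """Write reads in the collapsed tabular dialect (TSV, one header line)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in reads:
            fh.write("\t".join((
                r.chrom, str(r.start), r.strand, str(r.length),
                r.sequence or ".", r.sample, str(r.count), str(r.n_hits),
            )) + "\n")


def write_alignments_sam(reads: Iterable[MappedRead],
                         path: str | Path,
                         chrom_lengths: Mapping[str, int]) -> None:
    """Write reads as SAM with NH tags, RG sample tags, and ``_xCOUNT``
    names carrying the collapsed copy number."""
    reads = list(reads)
    samples = sorted({r.sample for r in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, r in enumerate(reads):
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = f"t{i:06d}_x{r.count}"
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = tid[r.chrom]
            seg.reference_start = r.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, r.length)]
            seg.query_sequence = r.sequence or ("N" * r.length)
            seg.set_tag("NH", r.n_hits)
            seg.set_tag("RG", r.sample)
            fh.write(seg)


# ---------------------------------------------------------------------------
# Region output: BED6 (0-based half-open) and GFF3 (1-based inclusive)

_REGION_ATTR_KEYS = ("register", "p_value", "phase_score", "rank")


def write_regions(regions: Sequence[GenomicInterval], path: str | Path,
                  format: str = "gff3",
                  attributes: Optional[Sequence[Mapping]] = None) -> None:
    """Persist called loci.  ``attributes`` is an optional parallel sequence
    of mappings carrying register, p_value, phase_score and rank."""
    if attributes is None:
        attributes = [{} for _ in regions]
    if len(attributes) != len(regions):
        raise ValueError("attributes must parallel regions")
    order = sorted(range(len(regions)),
                   key=lambda i: (regions[i].chrom, regions[i].start))
    with open(path, "w") as fh:
        if format == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for i in order:
                iv, at = regions[i], attributes[i]
                name = at.get("name", f"PHAS_{at.get('rank', i + 1)}")
                score = at.get("phase_score", 0.0)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                         f"{score:.4g}\t{iv.strand or '.'}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for i in order:
                iv, at = regions[i], attributes[i]
                name = at.get("name", f"PHAS_{at.get('rank', i + 1)}")
                attr = ";".join(
                    [f"ID={name}"]
                    + [f"{k}={at[k]}" for k in _REGION_ATTR_KEYS if k in at])
                fh.write(f"{iv.chrom}\tphaswindow\tsiRNA_locus\t"
                         f"{iv.start + 1}\t{iv.end}\t"
                         f"{at.get('phase_score', '.')}\t{iv.strand or '.'}\t.\t"
                         f"{attr}\n")
        else:
            raise FormatError(f"unknown region format: {format!r}")


def parse_regions(path: str | Path, format: str = "gff3"
                  ) -> list[tuple[GenomicInterval, dict]]:
    """Read back a BED6/GFF3 file written by :func:`write_regions`."""
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format == "bed":
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                     None if f[5] == "." else f[5])
                out.append((iv, {"name": f[3], "score": float(f[4])}))
            elif format == "gff3":
                iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]),
                                     None if f[6] == "." else f[6])
                attrs: dict = {}
                for kv in f[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k] = v
                for key, cast in (("register", int), ("p_value", float),
                                  ("phase_score", float), ("rank", int)):
                    if key in attrs:
                        attrs[key] = cast(attrs[key])
                out.append((iv, attrs))
            else:
                raise FormatError(f"unknown region format: {format!r}")
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
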