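"""miRNA trigger prediction and linkage to phasiRNAs.

phasiRNA production is initiated by miRNA-guided cleavage of the locus
transcript, so a candidate trigger is a miRNA with a high-complementarity
binding site near the phased reads.  Complementarity is scored with the
classical plant-target penalty scheme — mismatch 1, G:U wobble 0.5,
single-nucleotide bulge 1, all doubled within the functionally critical
miRNA positions 2–13 — and sites at penalty <= 3 are retained.  Cleavage
occurs opposite miRNA positions 10–11; a site is linked to a phasiRNA
when the cleavage position lies within 420 nt (20 phase cycles) of the
phasiRNA's 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .phasirna_extract import PhasiRNA, _revcomp
from .phas_scan import PhasRegion
from .sam_io import GenomicInterval

_RNA = set("ACGU")
_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

MISMATCH_COST = 1.0
WOBBLE_COST = 0.5
BULGE_COST = 1.0
CORE = (2, 13)  # 1-based miRNA positions with doubled costs
CORE_MULTIPLIER = 2.0


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA binding site on a locus sequence.

    Coordinates are 0-based on the scanned sequence's coordinate system
    (genomic when the scan was given genomic origins).  ``cleavage`` is
    the position opposite miRNA position 10, where the guided cut defines
    the phasing register.
    """

    mirna_id: str
    mirna_seq: str
    locus_id: str
    chrom: str
    strand: str
    site_start: int
    site_end: int
    cleavage: int
    penalty: float


@dataclass(frozen=True)
class TriggerCandidate:
    site: TargetSite
    phasirna: PhasiRNA
    distance: int
    in_register: bool


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= _RNA:
        raise ValueError(f"non-RNA characters in sequence: {seq!r}")
    return seq


def _position_cost(mirna_base: str, site_base: str, mirna_pos: int,
                   core: Tuple[int, int], core_multiplier: float) -> float:
    pair = (mirna_base, site_base)
    if pair in _PAIR:
        cost = 0.0
    elif pair in _WOBBLE:
        cost = WOBBLE_COST
    else:
        cost = MISMATCH_COST
    if core[0] <= mirna_pos <= core[1]:
        cost *= core_multiplier
    return cost


def target_score(mirna: str, site: str,
                 core: Tuple[int, int] = CORE,
                 core_multiplier: float = CORE_MULTIPLIER) -> float:
    """Penalty of a miRNA:target duplex.

    ``mirna`` is read 5'->3'; ``site`` is the target strand read 3'->5'
    so that equal indices pair.  Equal lengths score an ungapped duplex; a
    length difference of one introduces a single-nucleotide bulge (cost 1,
    doubled in the core) at the best-scoring position.  Sequences may be
    given in DNA alphabet; both are 19–24 nt.
    """
    m = _to_rna(mirna)
    t = _to_rna(site)
    if not (19 <= len(m) <= 24):
        raise ValueError(f"miRNA length {len(m)} outside 19-24 nt")
    if abs(len(m) - len(t)) > 1:
        raise ValueError("site length must be within 1 nt of miRNA length")
    if len(m) == len(t):
        return sum(_position_cost(m[i], t[i], i + 1, core, core_multiplier)
                   for i in range(len(m)))
    if len(t) == len(m) + 1:
        # bulged nucleotide on the target strand: skip one site position
        best = float("inf")
        for g in range(len(t)):
            t_del = t[:g] + t[g + 1:]
            pos = min(g + 1, len(m))  # miRNA position adjacent to the bulge
            cost = BULGE_COST
            if core[0] <= pos <= core[1]:
                cost *= core_multiplier
            cost += sum(_position_cost(m[i], t_del[i], i + 1, core,
                                       core_multiplier)
                        for i in range(len(m)))
            best = min(best, cost)
        return best
    # bulged nucleotide on the miRNA: skip one miRNA position
    best = float("inf")
    for g in range(len(m)):
        cost = BULGE_COST
        if core[0] <= g + 1 <= core[1]:
            cost *= core_multiplier
        mi = 0
        for i in range(len(m)):
            if i == g:
                continue
            cost += _position_cost(m[i], t[mi], i + 1, core, core_multiplier)
            mi += 1
        best = min(best, cost)
    return best


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# cost of pairing miRNA base (row) against target base (col), target read
# 3'->5'; complementary pairs cost 0, G:U wobbles 0.5, mismatches 1
_COSTTAB = np.ones((4, 4))
for _a, _b in _PAIR:
    _COSTTAB[_CODE[_a], _CODE[_b]] = 0.0
for _a, _b in _WOBBLE:
    _COSTTAB[_CODE[_a], _CODE[_b]] = WOBBLE_COST


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in _to_rna(seq)], dtype=np.int8)


def _scan_sequence(mseq: str, dna: str, max_penalty: float,
                   allow_bulge: bool) -> List[Tuple[int, int, float]]:
    """All (offset, site_length, penalty) with penalty <= max_penalty for
    one miRNA against one plus-strand sequence; numerically identical to
    :func:`target_score` evaluated at every offset and site length."""
    m = _encode(mseq)
    d = _encode(dna)
    L, n = len(m), len(d)
    if n < L - 1:
        return []
    w = np.array([CORE_MULTIPLIER if CORE[0] <= i + 1 <= CORE[1] else 1.0
                  for i in range(L)])
    ct = w[:, None] * _COSTTAB[m][:, d]  # (L, n) per-position costs
    out: List[Tuple[int, int, float]] = []

    # ungapped
    no = n - L + 1
    if no > 0:
        pen = np.zeros(no)
        for i in range(L):
            pen += ct[i, L - 1 - i: L - 1 - i + no]
        for o in np.nonzero(pen <= max_penalty)[0]:
            out.append((int(o), L, float(pen[o])))
    if not allow_bulge:
        return out

    bulge_w = lambda pos: (BULGE_COST * CORE_MULTIPLIER
                           if CORE[0] <= pos <= CORE[1] else BULGE_COST)

    # single bulged nucleotide on the target strand (site length L + 1)
    no = n - L
    if no > 0:
        A = np.stack([ct[i, L - i: L - i + no] for i in range(L)])
        B = np.stack([ct[i, L - 1 - i: L - 1 - i + no] for i in range(L)])
        prefA = np.vstack([np.zeros(no), np.cumsum(A, axis=0)])  # (L+1, no)
        sufB = np.vstack([np.cumsum(B[::-1], axis=0)[::-1], np.zeros(no)])
        bw = np.array([bulge_w(min(g + 1, L)) for g in range(L + 1)])
        pen = np.min(prefA + sufB + bw[:, None], axis=0)
        for o in np.nonzero(pen <= max_penalty)[0]:
            out.append((int(o), L + 1, float(pen[o])))

    # single bulged (unpaired) miRNA nucleotide (site length L - 1)
    no = n - L + 2
    if no > 0 and L >= 2:
        # i < g pairs ct[i, o+L-2-i]; i > g pairs ct[i, o+L-1-i]
        # row i of P is only read for i < g <= L-1; row 0 of S only for
        # g < 0 — both unused, padded to keep the stack rectangular
        P = np.stack([ct[i, L - 2 - i: L - 2 - i + no] if L - 2 - i >= 0
                      else np.zeros(no) for i in range(L)])
        S = np.stack([ct[i, L - 1 - i: L - 1 - i + no] if i >= 1
                      else np.zeros(no) for i in range(L)])
        prefP = np.vstack([np.zeros(no), np.cumsum(P, axis=0)])
        sufS = np.vstack([np.cumsum(S[::-1], axis=0)[::-1], np.zeros(no)])
        bw = np.array([bulge_w(g + 1) for g in range(L)])
        pen = np.min(prefP[:L] + sufS[1:] + bw[:, None], axis=0)
        ok = np.nonzero(pen <= max_penalty)[0]
        for o in ok:
            if o <= n - (L - 1):
                out.append((int(o), L - 1, float(pen[o])))
    return out


def extract_locus_sequences(genome: Mapping[str, str],
                            regions: Sequence[PhasRegion],
                            flank: int = 500
                            ) -> Tuple[Dict[str, str], Dict[str, Tuple[str, int]]]:
    """Plus-strand sequences of each locus +- ``flank`` nt, together with
    each scanned sequence's (chrom, genomic origin)."""
    seqs: Dict[str, str] = {}
    origins: Dict[str, Tuple[str, int]] = {}
    for i, reg in enumerate(regions):
        iv = reg.interval
        lid = f"{iv.chrom}_{iv.start}_{iv.end}"
        lo = max(0, iv.start - flank)
        hi = min(len(genome[iv.chrom]), iv.end + flank)
        seqs[lid] = genome[iv.chrom][lo:hi]
        origins[lid] = (iv.chrom, lo)
    return seqs, origins


def scan_targets(mirnas: Mapping[str, str],
                 loci: Mapping[str, str],
                 max_penalty: float = 3.0,
                 origins: Optional[Mapping[str, Tuple[str, int]]] = None,
                 allow_bulge: bool = True) -> List[TargetSite]:
    """All binding sites with penalty <= ``max_penalty`` on either strand
    of each locus sequence.

    For a plus-strand target transcript the miRNA pairs antiparallel, its
    5' end opposite the site's 3' end, so cleavage (opposite miRNA
    position 10) falls 10 nt from the site's right edge; on the minus
    strand, 10 nt from the left edge.  ``origins`` maps locus ids to
    (chrom, offset) so emitted coordinates are genomic.
    """
    sites: List[TargetSite] = []
    for mid, mseq_raw in mirnas.items():
        mseq = _to_rna(mseq_raw)
        for lid, dna in loci.items():
            chrom, origin = (origins or {}).get(lid, (lid, 0))
            n = len(dna)
            # plus-strand target: site read 3'->5' is the reversed slice
            for o, Ls, pen in _scan_sequence(mseq, dna, max_penalty,
                                             allow_bulge):
                sites.append(TargetSite(
                    mid, mseq, lid, chrom, "+",
                    origin + o, origin + o + Ls,
                    origin + o + Ls - 10, pen))
            # minus-strand target: transcript is the reverse complement
            for o, Ls, pen in _scan_sequence(mseq, _revcomp(dna),
                                             max_penalty, allow_bulge):
                gs = n - o - Ls  # genomic start of the site
                sites.append(TargetSite(
                    mid, mseq, lid, chrom, "-",
                    origin + gs, origin + gs + Ls,
                    origin + gs + 9, pen))
    # keep the best variant per (miRNA, locus, strand, cleavage)
    best: Dict[Tuple[str, str, str, int], TargetSite] = {}
    for s in sites:
        key = (s.mirna_id, s.locus_id, s.strand, s.cleavage)
        if key not in best or s.penalty < best[key].penalty:
            best[key] = s
    return sorted(best.values(),
                  key=lambda s: (s.locus_id, s.site_start, s.mirna_id, s.strand))


def five_prime_end(phasirna: PhasiRNA, length: int = 21) -> int:
    """Genomic coordinate of a phasiRNA's 5' end (right edge for
    minus-strand species)."""
    return phasirna.start if phasirna.strand == "+" else phasirna.start + length - 1


def link_triggers(sites: Sequence[TargetSite],
                  phasirnas: Sequence[PhasiRNA],
                  max_distance: int = 420,
                  phase_len: int = 21) -> List[TriggerCandidate]:
    """Retain (site, phasiRNA) pairs on the same chromosome whose cleavage
    position lies within ``max_distance`` nt (inclusive) of the phasiRNA
    5' end.  ``in_register`` flags distances that are multiples of the
    phase length (informational; not filtered on)."""
    out: List[TriggerCandidate] = []
    for site in sites:
        for p in phasirnas:
            if p.chrom != site.chrom:
                continue
            d = abs(site.cleavage - five_prime_end(p, phase_len))
            if d <= max_distance:
                out.append(TriggerCandidate(site, p, d, d % phase_len == 0))
    return out
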