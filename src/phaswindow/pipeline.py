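"""End-to-end orchestration: collapse -> scan -> extract -> triggers ->
tabulation, with a manifest of applied thresholds and per-stage record
counts so the attrition at every filter is auditable on any run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .abundance import counts_to_frame, normalize, size_factors
from .phas_scan import (PhasRegion, ScanParams, call_regions, scan)
from .phasirna_extract import (PhasiRNA, extract_phasirnas,
                               filter_by_phase_count, phase_profile,
                               scaled_min_total)
from .read_model import (CollapsedReadSet, ReadFilterParams, collapse,
                         filter_for_phasing, filter_length)
from .sam_io import read_alignments, read_fasta, write_regions
from .trigger_link import (TriggerCandidate, extract_locus_sequences,
                           link_triggers, scan_targets)

logger = logging.getLogger("phaswindow")


@dataclass
class PipelineConfig:
    """All thresholds in one place; defaults are the method's canonical
    values (210/21 window, p < 1e-6, top 50, >3000 pooled counts over 7
    samples, <= 2 phases, 420 nt trigger proximity, penalty <= 3)."""

    reads: str = ""
    reads_format: str = "table"
    genome: Optional[str] = None
    mirnas: Optional[str] = None
    out_dir: str = "phaswindow_out"
    filters: ReadFilterParams = field(default_factory=ReadFilterParams)
    scan: ScanParams = field(default_factory=ScanParams)
    min_total: int = 3000
    reference_samples: int = 7
    scale_min_total: bool = True
    max_phases: int = 2
    phase_bin_frac: float = 0.10
    max_penalty: float = 3.0
    max_distance: int = 420
    flank: int = 500

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = ReadFilterParams(**d["filters"])
        if "scan" in d:
            d["scan"] = ScanParams(**d["scan"])
        return cls(**d)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: Dict[str, str]
    counts: Dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    manifest: RunManifest
    regions: List[PhasRegion]
    retained_regions: List[PhasRegion]
    phasirnas: List[PhasiRNA]
    triggers: List[TriggerCandidate]
    counts: pd.DataFrame


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig,
            write_files: bool = True) -> PipelineResult:
    """Execute the stages in order; any stage failure aborts with the
    stage named.  Returns all stage outputs plus the manifest."""
    counts: Dict[str, int] = {}
    checksums: Dict[str, str] = {}
    stage = "input"
    try:
        for name, p in (("reads", config.reads), ("genome", config.genome),
                        ("mirnas", config.mirnas)):
            if p:
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input: {p}")
                checksums[name] = _sha256(p)

        stage = "collapse"
        alignments = read_alignments(config.reads, config.reads_format)
        collapsed = collapse(alignments)
        counts["species_collapsed"] = len(collapsed)
        counts["reads_mapped"] = collapsed.total_mapped

        stage = "filter_length"
        lenfilt = filter_length(collapsed, config.filters)
        counts["species_length_filtered"] = len(lenfilt)

        stage = "filter_for_phasing"
        phasing_set = filter_for_phasing(lenfilt, config.filters)
        counts["species_phasing_eligible"] = len(phasing_set)

        stage = "scan"
        hits = scan(phasing_set, config.scan)
        counts["significant_window_registers"] = len(hits)

        stage = "call_regions"
        uncapped = replace(config.scan, top_k=10 ** 9)
        all_regions = call_regions(hits, phasing_set, uncapped)
        regions = all_regions[:config.scan.top_k]
        counts["regions_merged"] = len(all_regions)
        counts["regions_top_k"] = len(regions)

        stage = "extract_phasirnas"
        n_samples = max(len(phasing_set.samples), 1)
        min_total = scaled_min_total(config.min_total, n_samples,
                                     config.reference_samples) \
            if config.scale_min_total else float(config.min_total)
        genome = read_fasta(config.genome) if config.genome else None
        phasirnas: List[PhasiRNA] = []
        profiles = []
        for reg in regions:
            phasirnas.extend(extract_phasirnas(
                reg, phasing_set, min_total=min_total, params=config.scan,
                genome=genome))
            profiles.append(phase_profile(reg, phasing_set, config.scan))
        counts["phasirnas_abundant"] = len(phasirnas)

        stage = "phase_count_filter"
        kept_ids, decisions = filter_by_phase_count(
            profiles, config.max_phases, config.phase_bin_frac)
        kept = set(kept_ids)
        retained_regions = [
            reg for reg, prof in zip(regions, profiles)
            if prof.locus_id in kept]
        phasirnas = [p for p in phasirnas if p.locus_id in kept]
        counts["loci_phase_filtered"] = len(retained_regions)
        counts["phasirnas_retained"] = len(phasirnas)

        stage = "triggers"
        triggers: List[TriggerCandidate] = []
        if config.genome and config.mirnas and retained_regions:
            mirnas = read_fasta(config.mirnas)
            seqs, origins = extract_locus_sequences(genome, retained_regions,
                                                    config.flank)
            sites = scan_targets(mirnas, seqs, config.max_penalty,
                                 origins=origins)
            counts["target_sites"] = len(sites)
            triggers = link_triggers(sites, phasirnas, config.max_distance,
                                     config.scan.s)
        counts["trigger_pairs"] = len(triggers)

        stage = "tabulate"
        matrix = counts_to_frame(
            {f"{p.chrom}_{p.start}_{p.strand}": p.sample_counts
             for p in phasirnas}) if phasirnas else pd.DataFrame()

        manifest = RunManifest(__version__, _config_dict(config),
                               checksums, counts)
        if write_files:
            _write_outputs(config, manifest, regions, retained_regions,
                           phasirnas, profiles, triggers, matrix)
        return PipelineResult(manifest, regions, retained_regions,
                              phasirnas, triggers, matrix)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_outputs(config: PipelineConfig, manifest: RunManifest,
                   regions: Sequence[PhasRegion],
                   retained: Sequence[PhasRegion],
                   phasirnas: Sequence[PhasiRNA],
                   profiles, triggers: Sequence[TriggerCandidate],
                   matrix: pd.DataFrame) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attrs = [{"name": f"PHAS_{r.rank}", "register": r.register,
              "p_value": f"{r.p_value:.3g}",
              "phase_score": f"{r.phase_score:.4f}", "rank": r.rank}
             for r in regions]
    write_regions([r.interval for r in regions], out / "regions.gff3",
                  "gff3", attrs)
    with open(out / "regions.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tregister\tphase0\tp_value\t"
                 "phase_score\trank\tn_windows\tk\tretained\n")
        kept = {id(r) for r in retained}
        for r in regions:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                     f"{r.interval.end}\t{r.register}\t{r.phase0}\t"
                     f"{r.p_value:.6g}\t{r.phase_score:.4f}\t{r.rank}\t"
                     f"{r.n_windows}\t{r.k}\t{int(id(r) in kept)}\n")
    samples = sorted({s for p in phasirnas for s in p.sample_counts})
    with open(out / "phasirnas.tsv", "w") as fh:
        fh.write("locus\tchrom\tstart\tstrand\tsequence\t"
                 + "\t".join(samples) + "\ttotal\n")
        for p in phasirnas:
            row = [p.locus_id, p.chrom, str(p.start), p.strand,
                   p.sequence or "."]
            row += [str(p.sample_counts.get(s, 0)) for s in samples]
            row.append(str(p.total_count))
            fh.write("\t".join(row) + "\n")
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("locus\t" + "\t".join(f"r{i}" for i in range(1, 22)) + "\n")
        for prof in profiles:
            fh.write(prof.locus_id + "\t"
                     + "\t".join(f"{a:g}" for a in prof.abundance) + "\n")
    with open(out / "triggers.tsv", "w") as fh:
        fh.write("mirna\tlocus\tphasirna\tcleavage\tdistance\tpenalty\t"
                 "in_register\n")
        for t in triggers:
            fh.write(f"{t.site.mirna_id}\t{t.site.locus_id}\t"
                     f"{t.phasirna.chrom}_{t.phasirna.start}_"
                     f"{t.phasirna.strand}\t{t.site.cleavage}\t"
                     f"{t.distance}\t{t.site.penalty:g}\t"
                     f"{int(t.in_register)}\n")
    if not matrix.empty:
        matrix.to_csv(out / "counts.tsv", sep="\t")
        if matrix.shape[1] >= 2:
            try:
                sf = size_factors(matrix, pseudocount=0.0)
            except Exception:
                sf = size_factors(matrix, pseudocount=1.0)
            sf.to_csv(out / "size_factors.tsv", sep="\t")
            normalize(matrix, sf).to_csv(out / "counts_normalized.tsv",
                                         sep="\t")
    manifest.to_json(out / "manifest.json")
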