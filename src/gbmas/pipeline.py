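"""End-to-end run orchestration: sort -> align -> count -> cutoffs -> calls.

Given a FASTQ, a panel and a sample sheet, the pipeline executes the four
analysis stages plus cutoff derivation and calling, writes all tabular
outputs, and produces a run report whose totals reconcile with the
stage-level conservation counts. Runs are deterministic: identical inputs
yield byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

from .align import AlignmentParams, observe_sites
from .call import (CallingConfig, call_genotypes, call_rate, count_alleles,
                   cutoff_frame, derive_cutoffs)
from .panel import Panel, load_panel
from .sort import assign_marker, demultiplex, read_fastq

log = logging.getLogger("gbmas")


@dataclass
class RunConfig:
    fastq: Path
    panel_tsv: Path
    panel_fasta: Path
    sample_sheet: Path
    outdir: Path
    max_barcode_mismatch: int = 1
    max_primer_mismatch: int = 2
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    calling: CallingConfig = field(default_factory=CallingConfig)
    strip_a_adapter: bool = False
    try_reverse_complement: bool = False
    log_level: str = "INFO"


@dataclass
class RunReport:
    outdir: Path
    stats: Dict
    counts_path: Path
    calls_path: Path
    report_json: Path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis run; see module docstring.

    Raises a configuration error before any work if an input path is
    missing; stage failures abort with the failing stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for p in (config.fastq, config.panel_tsv, config.panel_fasta, config.sample_sheet):
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel_tsv, config.panel_fasta,
                       sample_sheet_path=config.sample_sheet,
                       max_barcode_mismatch=config.max_barcode_mismatch,
                       max_primer_mismatch=config.max_primer_mismatch)
    log.info("panel: %d markers, %d samples", len(panel.markers), len(panel.samples))

    log.info("stage 1: demultiplexing %s", config.fastq)
    by_sample, stats = demultiplex(
        read_fastq(config.fastq), panel.samples, config.max_barcode_mismatch,
        try_reverse_complement=config.try_reverse_complement,
        strip_a_adapter=config.strip_a_adapter, adapters=panel.adapters)

    log.info("stage 2: marker assignment")
    sorted_reads = []
    for sample_id in panel.sample_ids:
        assigned, stats = assign_marker(sample_id, by_sample[sample_id], panel,
                                        config.max_primer_mismatch, stats=stats)
        sorted_reads.extend(assigned)

    log.info("stage 3: alignment and site observation (%d reads)", len(sorted_reads))
    marker_of = {m.marker_id: m for m in panel.markers}
    observations = []
    rejected_alignments = 0
    for sr in sorted_reads:
        obs = observe_sites(sr, marker_of[sr.marker_id], config.alignment)
        if obs:
            observations.extend(obs)
        else:
            rejected_alignments += 1

    log.info("stage 4: allele counting, cutoffs and calls")
    counts = count_alleles(observations, panel=panel)
    cutoffs = derive_cutoffs(counts, panel.samples, panel, config.calling)
    calls = call_genotypes(counts, panel, cutoffs, config.calling)
    rates = call_rate(calls)

    counts_path = outdir / "allele_counts.tsv"
    calls_path = outdir / "genotype_calls.tsv"
    counts.to_csv(counts_path, sep="\t", index=False)
    calls.to_csv(calls_path, sep="\t", index=False)
    cutoff_frame(cutoffs).to_csv(outdir / "cutoffs.tsv", sep="\t", index=False)
    rates.to_csv(outdir / "call_rates.tsv", sep="\t", index=False)

    stage_totals = {
        "total_reads": stats.total_reads,
        "assigned_to_sample": stats.assigned_to_sample,
        "unassigned_barcode": stats.unassigned_barcode,
        "ambiguous_barcode": stats.ambiguous_barcode,
        "assigned_to_marker": stats.assigned_to_marker,
        "unassigned_marker": stats.unassigned_marker,
        "ambiguous_marker": stats.ambiguous_marker,
        "rejected_alignments": rejected_alignments,
        "accepted_reads": len(sorted_reads) - rejected_alignments,
    }
    report = {
        "config": _jsonable(config),
        "stage_totals": stage_totals,
        "per_sample_reads": dict(sorted(stats.per_sample.items())),
        "cutoffs": _jsonable(list(cutoffs)),
        "call_rates_percent": {r.marker_id: r.call_rate_percent
                               for r in rates.itertuples(index=False)},
    }
    report_json = outdir / "report.json"
    report_json.write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(_human_report(report))
    log.info("run complete: %s", outdir)
    return RunReport(outdir=outdir, stats=report, counts_path=counts_path,
                     calls_path=calls_path, report_json=report_json)


def _human_report(report: Dict) -> str:
    t = report["stage_totals"]
    lines = [
        "GBMAS run report",
        "================",
        f"reads in:                 {t['total_reads']}",
        f"  assigned to samples:    {t['assigned_to_sample']}",
        f"  unassigned barcode:     {t['unassigned_barcode']}",
        f"  ambiguous barcode:      {t['ambiguous_barcode']}",
        f"  assigned to markers:    {t['assigned_to_marker']}",
        f"  unassigned marker:      {t['unassigned_marker']}",
        f"  ambiguous marker:       {t['ambiguous_marker']}",
        f"  rejected alignments:    {t['rejected_alignments']}",
        f"  reads in pileups:       {t['accepted_reads']}",
        "",
        "cutoffs (percent favorable of in-run positive-control minimum):",
    ]
    for c in report["cutoffs"]:
        lines.append(f"  {c['marker_id']}/{c['site_id']}: "
                     f"{c['cutoff_percent']:.1f}% "
                     f"(controls: {', '.join(c['source_samples'])})")
    lines.append("")
    lines.append("call rates:")
    for mid, rate in sorted(report["call_rates_percent"].items()):
        lines.append(f"  {mid}: {rate:.1f}%")
    return "\n".join(lines) + "\n"
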