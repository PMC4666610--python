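"""Read sorting: barcode demultiplexing and forward-primer marker assignment.

These are the first two pipeline stages. Reads are assumed to start at the
sample barcode (the sequencer strips the A adapter); a config flag handles
runs where the adapter is retained. Both stages match a fixed-length prefix
by Hamming distance — substitutions only, no indels — against the known
barcodes (stage 1) or each marker's M13-tail + forward-primer prefix
(stage 2). A read is assigned to the unique best match within tolerance;
ties and over-tolerance reads land in the unassigned/ambiguous bins, and
both stages conserve read counts exactly.

Mixed-length barcodes (10-12 nt) are each tried at their own length; at
equal mismatch count the longest match wins, and an unresolved tie leaves
the read unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .dna import hamming_within, revcomp
from .panel import BarcodeRecord, Panel, PanelValidationError
from .primers import AdapterSet

Read = Tuple[str, str]  # (read_id, sequence)


@dataclass(frozen=True)
class SortedRead:
    """A read attributed to (sample, marker) with its prefix segments trimmed."""

    sample_id: str
    marker_id: str
    insert_sequence: str
    read_id: str
    prefix_mismatches: int


@dataclass
class SortStats:
    """Per-stage read accounting; all bins sum back to the input count."""

    total_reads: int = 0
    per_sample: Dict[str, int] = field(default_factory=dict)
    per_pair: Dict[Tuple[str, str], int] = field(default_factory=dict)
    unassigned_barcode: int = 0
    ambiguous_barcode: int = 0
    unassigned_marker: int = 0
    ambiguous_marker: int = 0
    quality_filtered: int = 0

    @property
    def assigned_to_sample(self) -> int:
        return sum(self.per_sample.values())

    @property
    def assigned_to_marker(self) -> int:
        return sum(self.per_pair.values())


def read_fastq(path) -> Iterator[Read]:
    """Yield (id, upper-case sequence) from a FASTQ file (gzip-transparent)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()


def read_fastq_with_quality(path) -> Iterator[Tuple[str, str, Optional[str]]]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper(), entry.quality


def _check_separability(prefixes: Sequence[Tuple[str, str]], tolerance: int, what: str) -> None:
    for i, (id_a, a) in enumerate(prefixes):
        for id_b, b in prefixes[i + 1:]:
            n = min(len(a), len(b))
            if hamming_within(a[:n], b[:n], tolerance) <= tolerance:
                raise PanelValidationError(
                    f"{what} tolerance {tolerance} would make {id_a!r} and {id_b!r} "
                    f"systematically ambiguous (prefix distance <= {tolerance})")


def _best_prefix_match(seq: str, candidates: Sequence[Tuple[str, str]],
                       max_mismatch: int) -> Tuple[Optional[str], Optional[str], int]:
    """Unique best candidate whose prefix matches ``seq`` within tolerance.

    Returns (candidate_id, matched_prefix, mismatches); (None, None, -1) for
    no match within tolerance and (None, None, -2) for an unresolved tie.
    Ranking is (mismatches asc, prefix length desc); equal on both -> tie.
    """
    best_id: Optional[str] = None
    best_prefix: Optional[str] = None
    best_mm = max_mismatch + 1
    best_len = -1
    tied = False
    for cand_id, prefix in candidates:
        if len(seq) < len(prefix):
            continue
        mm = hamming_within(seq[:len(prefix)], prefix, max_mismatch)
        if mm > max_mismatch:
            continue
        if mm < best_mm or (mm == best_mm and len(prefix) > best_len):
            best_id, best_prefix, best_mm, best_len = cand_id, prefix, mm, len(prefix)
            tied = False
        elif mm == best_mm and len(prefix) == best_len and cand_id != best_id:
            tied = True
    if best_id is None:
        return None, None, -1
    if tied:
        return None, None, -2
    return best_id, best_prefix, best_mm


def _mean_quality(quality: Optional[str]) -> float:
    if not quality:
        return float("inf")
    return sum(ord(c) - 33 for c in quality) / len(quality)


def demultiplex(reads: Iterable[Read], barcodes: Sequence[BarcodeRecord],
                max_barcode_mismatch: int = 1,
                try_reverse_complement: bool = False,
                strip_a_adapter: bool = False,
                adapters: AdapterSet = AdapterSet(),
                stats: Optional[SortStats] = None,
                ) -> Tuple[Dict[str, List[Read]], SortStats]:
    """Sort reads into samples by best barcode-prefix match; strip the barcode.

    Raises a configuration error up front if the tolerance is not below the
    minimum pairwise barcode distance (which would guarantee ambiguity).
    """
    _check_separability([(b.sample_id, b.barcode) for b in barcodes],
                        max_barcode_mismatch, "barcode")
    exact: Dict[str, BarcodeRecord] = {b.barcode: b for b in barcodes}
    lengths = sorted({len(b.barcode) for b in barcodes}, reverse=True)
    candidates = [(b.sample_id, b.barcode) for b in barcodes]
    by_sample: Dict[str, BarcodeRecord] = {b.sample_id: b for b in barcodes}

    stats = stats or SortStats()
    out: Dict[str, List[Read]] = {b.sample_id: [] for b in barcodes}
    a_adapter = adapters.ion_a_adapter

    for read_id, seq in reads:
        stats.total_reads += 1
        if strip_a_adapter and seq.startswith(a_adapter):
            seq = seq[len(a_adapter):]
        attempts = (seq, revcomp(seq)) if try_reverse_complement else (seq,)
        assigned = False
        tie_seen = False
        for attempt in attempts:
            # exact match first (longest barcode length wins by construction)
            hit = None
            for L in lengths:
                rec = exact.get(attempt[:L])
                if rec is not None:
                    hit = rec
                    break
            if hit is None and max_barcode_mismatch > 0:
                sid, prefix, mm = _best_prefix_match(attempt, candidates, max_barcode_mismatch)
                if mm == -2:
                    tie_seen = True
                if sid is not None:
                    hit = by_sample[sid]
            if hit is not None:
                out[hit.sample_id].append((read_id, attempt[len(hit.barcode):]))
                stats.per_sample[hit.sample_id] = stats.per_sample.get(hit.sample_id, 0) + 1
                assigned = True
                break
        if not assigned:
            if tie_seen:
                stats.ambiguous_barcode += 1
            else:
                stats.unassigned_barcode += 1
    return out, stats


def assign_marker(sample_id: str, reads: Iterable[Read], panel: Panel,
                  max_primer_mismatch: int = 2,
                  trim_trailing_adapter: bool = True,
                  trailing_adapter_mismatch: int = 2,
                  stats: Optional[SortStats] = None,
                  ) -> Tuple[List[SortedRead], SortStats]:
    """Subdivide one sample's demultiplexed reads into markers.

    The expected prefix for each marker is the M13 tail plus its forward
    primer; matching is Hamming over that prefix length. Assigned reads have
    the prefix stripped; a trailing P1/B adapter (and anything after it) is
    trimmed when it matches the expected suffix within tolerance, so the
    remaining insert aligns end-to-end against the reference minus its
    forward-primer region.
    """
    adapters = panel.adapters
    candidates = [(m.marker_id, adapters.m13_tail + m.forward_primer) for m in panel.markers]
    _check_separability(candidates, max_primer_mismatch, "forward-primer")
    exact = {prefix: mid for mid, prefix in candidates}
    lengths = sorted({len(p) for _, p in candidates}, reverse=True)
    trp1 = adapters.trp1_adapter

    stats = stats or SortStats()
    out: List[SortedRead] = []
    for read_id, seq in reads:
        mid: Optional[str] = None
        prefix: Optional[str] = None
        mm = 0
        for L in lengths:
            cand = exact.get(seq[:L])
            if cand is not None:
                mid, prefix = cand, seq[:L]
                break
        if mid is None and max_primer_mismatch > 0:
            mid, prefix, mm = _best_prefix_match(seq, candidates, max_primer_mismatch)
        if mid is None:
            if mm == -2:
                stats.ambiguous_marker += 1
            else:
                stats.unassigned_marker += 1
            continue
        insert = seq[len(prefix):]
        if trim_trailing_adapter and len(insert) >= len(trp1):
            tail = insert[-len(trp1):]
            if hamming_within(tail, trp1, trailing_adapter_mismatch) <= trailing_adapter_mismatch:
                insert = insert[:-len(trp1)]
        if not insert:
            stats.unassigned_marker += 1
            continue
        out.append(SortedRead(sample_id=sample_id, marker_id=mid,
                              insert_sequence=insert, read_id=read_id,
                              prefix_mismatches=mm))
        key = (sample_id, mid)
        stats.per_pair[key] = stats.per_pair.get(key, 0) + 1
    return out, stats


def sort_reads(reads: Iterable[Read], panel: Panel,
               max_barcode_mismatch: int = 1,
               max_primer_mismatch: int = 2,
               try_reverse_complement: bool = False,
               strip_a_adapter: bool = False,
               ) -> Tuple[List[SortedRead], SortStats]:
    """Run both sorting stages; one SortStats covers the whole sort."""
    by_sample, stats = demultiplex(
        reads, panel.samples, max_barcode_mismatch,
        try_reverse_complement=try_reverse_complement,
        strip_a_adapter=strip_a_adapter, adapters=panel.adapters)
    sorted_reads: List[SortedRead] = []
    for sample_id in panel.sample_ids:
        assigned, stats = assign_marker(sample_id, by_sample[sample_id], panel,
                                        max_primer_mismatch, stats=stats)
        sorted_reads.extend(assigned)
    return sorted_reads, stats


def sort_stats_frame(stats: SortStats):
    """Flatten SortStats into a tidy per-(sample, marker) table plus totals."""
    import pandas as pd

    rows = [{"sample_id": s, "marker_id": m, "n_reads": n}
            for (s, m), n in sorted(stats.per_pair.items())]
    return pd.DataFrame(rows, columns=["sample_id", "marker_id", "n_reads"])
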