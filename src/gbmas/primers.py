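"""Fusion-primer construction for the two-step amplicon library build.

The library structure is a two-round PCR. In the first (multiplex) round
each locus-specific forward primer carries a universal M13-derived tail at
its 5' end and each reverse primer carries the truncated P1/B adapter. In
the second round a per-sample fusion primer — sequencing A adapter, sample
barcode, then the same M13 tail — converts every first-round amplicon into
a barcoded, sequencer-ready fragment. After the instrument strips the A
adapter, a read therefore starts at the barcode and runs:

    barcode | M13 tail | forward primer | insert | revcomp(reverse primer) | P1/B

which is exactly the structure the simulator emits and the read sorter
expects to trim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .dna import is_dna, revcomp

#: Universal M13-derived tail appended 5' of every locus-specific forward primer.
M13_TAIL = "GATGTAAAACGACGGCCAGTG"
#: Truncated P1/B adapter, 5' of every reverse primer and the sole PCR-2 reverse primer.
TRP1_ADAPTER = "CCTCTCTATGGGCAGTCGGTGAT"
#: Standard sequencing A adapter leading the barcoded PCR-2 forward fusion primer.
ION_A_ADAPTER = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"

BARCODE_MIN_LEN = 10
BARCODE_MAX_LEN = 12


@dataclass(frozen=True)
class AdapterSet:
    """The three constant adapter/tail sequences used to build fusion primers."""

    m13_tail: str = M13_TAIL
    trp1_adapter: str = TRP1_ADAPTER
    ion_a_adapter: str = ION_A_ADAPTER

    def __post_init__(self) -> None:
        for name in ("m13_tail", "trp1_adapter", "ion_a_adapter"):
            seq = getattr(self, name)
            if not is_dna(seq):
                raise ValueError(f"adapter {name} must be a non-empty DNA string, got {seq!r}")


@dataclass(frozen=True)
class FusionPrimerSet:
    """All ordered oligos for one marker panel.

    ``pcr1`` maps marker_id -> (tailed forward, tailed reverse); ``pcr2_forward``
    maps sample_id -> barcoded fusion primer; ``pcr2_reverse`` is shared.
    """

    pcr1: dict
    pcr2_forward: dict
    pcr2_reverse: str


def build_pcr1_primers(marker, adapters: AdapterSet = AdapterSet()) -> Tuple[str, str]:
    """Tail the locus-specific primer pair for the first (multiplex) PCR.

    Pure string concatenation: ``m13_tail + forward`` and ``trp1 + reverse``.
    """
    if not marker.forward_primer or not marker.reverse_primer:
        raise ValueError(f"marker {marker.marker_id!r} has an empty locus-specific primer")
    return (
        adapters.m13_tail + marker.forward_primer,
        adapters.trp1_adapter + marker.reverse_primer,
    )


def build_pcr2_forward(barcode: str, adapters: AdapterSet = AdapterSet()) -> str:
    """Barcoded forward fusion primer for the second PCR: A adapter + barcode + M13."""
    if not (BARCODE_MIN_LEN <= len(barcode) <= BARCODE_MAX_LEN):
        raise ValueError(
            f"barcode length must be in [{BARCODE_MIN_LEN}, {BARCODE_MAX_LEN}], "
            f"got {len(barcode)} ({barcode!r})"
        )
    if not is_dna(barcode):
        raise ValueError(f"barcode must be DNA over ACGT, got {barcode!r}")
    return adapters.ion_a_adapter + barcode + adapters.m13_tail


def build_fusion_primer_set(panel, adapters: AdapterSet | None = None) -> FusionPrimerSet:
    """Construct every oligo needed to order a panel's primer sets."""
    adapters = adapters or panel.adapters
    return FusionPrimerSet(
        pcr1={m.marker_id: build_pcr1_primers(m, adapters) for m in panel.markers},
        pcr2_forward={s.sample_id: build_pcr2_forward(s.barcode, adapters) for s in panel.samples},
        pcr2_reverse=adapters.trp1_adapter,
    )


def expected_read_layout(marker, barcode: str, adapters: AdapterSet = AdapterSet()) -> List[Tuple[str, str]]:
    """5'->3' segment structure of a sequenced read after A-adapter removal.

    Returns ordered (segment_name, sequence) pairs. The ``insert`` is the
    amplicon portion between the two locus primers; a dominant null allele
    manifests as absent reads, not as a different layout.
    """
    fwd = marker.forward_primer
    rev = marker.reverse_primer
    insert = marker.reference_amplicon[len(fwd): len(marker.reference_amplicon) - len(rev)]
    return [
        ("barcode", barcode),
        ("m13_tail", adapters.m13_tail),
        ("forward_primer", fwd),
        ("insert", insert),
        ("reverse_primer_rc", revcomp(rev)),
        ("trp1_adapter", adapters.trp1_adapter),
    ]


def read_sequence(marker, barcode: str, adapters: AdapterSet = AdapterSet(),
                  amplicon: str | None = None) -> str:
    """Full expected read sequence for one amplicon haplotype.

    ``amplicon`` overrides the marker's reference amplicon (used by the
    simulator to emit allele-resolved templates); it must keep the primer
    ends intact.
    """
    amp = amplicon if amplicon is not None else marker.reference_amplicon
    return barcode + adapters.m13_tail + amp + adapters.trp1_adapter
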