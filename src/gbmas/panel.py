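"""Marker panel, sample sheet and control definitions plus their file formats.

A panel is a TSV of marker rows (primers, mode, genome specificity, variant
sites) paired with a FASTA of reference amplicons keyed by marker_id. The
reference amplicon is the primer-to-primer sequence of the known positive
accession, so it starts with the forward primer, ends with the reverse
complement of the reverse primer, and carries the favorable base at every
annotated site. Variant positions are 1-based on that amplicon, inclusive,
matching the field convention of annotating the base position in the marker
name (e.g. SNP54).

The sample sheet is a TSV mapping sample_id -> barcode with optional
positive/negative control annotations per marker. Barcodes must stay
pairwise separable at the demultiplexing tolerance: two barcodes whose
prefixes (over the shorter length) are within ``max_barcode_mismatch`` of
each other would make assignment systematically ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import is_dna, prefix_distance, revcomp
from .primers import AdapterSet, BARCODE_MAX_LEN, BARCODE_MIN_LEN

MODES = ("codominant", "dominant_null")
SPECIFICITIES = ("genome_specific", "semi_specific", "non_specific")

#: genome specificity -> number of co-amplified genome copies (hexaploid wheat:
#: a genome-specific primer amplifies one subgenome, a semi-specific one two,
#: a non-specific one all three).
COPIES_BY_SPECIFICITY = {"genome_specific": 1, "semi_specific": 2, "non_specific": 3}

AMPLICON_MIN_LEN = 80
AMPLICON_MAX_LEN = 200
PRIMER_MIN_LEN = 17
PRIMER_MAX_LEN = 21

PANEL_COLUMNS = ["marker_id", "fwd_primer", "rev_primer", "mode", "specificity", "sites"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "barcode", "pos_control_for", "neg_control_for"]


class PanelFormatError(ValueError):
    """A panel/sample-sheet file is structurally malformed (missing columns etc.)."""


class PanelValidationError(ValueError):
    """A structurally well-formed panel violates a domain invariant."""


@dataclass(frozen=True)
class Finding:
    """One violated invariant, as data (``validate_panel`` never raises)."""

    subject: str  # marker_id / sample_id / pair description
    rule: str     # short machine-readable rule name
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.rule}] {self.subject}: {self.message}"


@dataclass(frozen=True)
class VariantSite:
    site_id: str
    position: int  # 1-based on the reference amplicon, inclusive
    favorable_base: str
    wild_type_base: str
    trait_label: str = ""


@dataclass(frozen=True)
class MarkerDefinition:
    marker_id: str
    forward_primer: str
    reverse_primer: str
    reference_amplicon: str
    sites: tuple
    mode: str = "codominant"
    specificity: str = "genome_specific"

    @property
    def copies_coamplified(self) -> int:
        return COPIES_BY_SPECIFICITY[self.specificity]

    @property
    def insert(self) -> str:
        """Amplicon portion between the two locus primers."""
        return self.reference_amplicon[len(self.forward_primer):
                                       len(self.reference_amplicon) - len(self.reverse_primer)]


@dataclass(frozen=True)
class BarcodeRecord:
    sample_id: str
    barcode: str
    is_positive_control_for: tuple = ()
    is_negative_control_for: tuple = ()


@dataclass
class Panel:
    markers: List[MarkerDefinition]
    samples: List[BarcodeRecord] = field(default_factory=list)
    adapters: AdapterSet = field(default_factory=AdapterSet)

    def marker(self, marker_id: str) -> MarkerDefinition:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    @property
    def marker_ids(self) -> List[str]:
        return [m.marker_id for m in self.markers]

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]


# ---------------------------------------------------------------------------
# validation

def _validate_marker(m: MarkerDefinition) -> List[Finding]:
    out: List[Finding] = []

    def bad(rule: str, msg: str) -> None:
        out.append(Finding(m.marker_id, rule, msg))

    for name, p in (("forward", m.forward_primer), ("reverse", m.reverse_primer)):
        if not is_dna(p):
            bad("primer_alphabet", f"{name} primer is not a DNA string over ACGT")
        elif not (PRIMER_MIN_LEN <= len(p) <= PRIMER_MAX_LEN):
            bad("primer_length",
                f"{name} primer length {len(p)} outside [{PRIMER_MIN_LEN}, {PRIMER_MAX_LEN}]")
    if not is_dna(m.reference_amplicon):
        bad("amplicon_alphabet", "reference amplicon is not a DNA string over ACGT")
        return out
    L = len(m.reference_amplicon)
    if not (AMPLICON_MIN_LEN <= L <= AMPLICON_MAX_LEN):
        bad("amplicon_length",
            f"amplicon length {L} outside [{AMPLICON_MIN_LEN}, {AMPLICON_MAX_LEN}]")
    if not m.reference_amplicon.startswith(m.forward_primer):
        bad("amplicon_fwd_anchor", "reference amplicon does not start with the forward primer")
    if not m.reference_amplicon.endswith(revcomp(m.reverse_primer)):
        bad("amplicon_rev_anchor",
            "reference amplicon does not end with the reverse complement of the reverse primer")
    if m.mode not in MODES:
        bad("mode", f"unknown mode {m.mode!r}")
    if m.specificity not in SPECIFICITIES:
        bad("specificity", f"unknown specificity {m.specificity!r}")
    if m.mode == "codominant" and not m.sites:
        bad("sites_required", "codominant marker needs at least one variant site")

    positions = [s.position for s in m.sites]
    if len(set(positions)) != len(positions):
        bad("site_positions_unique", f"duplicate site positions {sorted(positions)}")
    for s in m.sites:
        if s.position < 1:
            bad("site_position", f"site {s.site_id}: position must be >=1, got {s.position}")
            continue
        if s.position > L:
            bad("site_position",
                f"site {s.site_id}: position {s.position} beyond amplicon length {L}")
            continue
        if s.position <= len(m.forward_primer) or s.position > L - len(m.reverse_primer):
            bad("site_in_primer",
                f"site {s.site_id}: position {s.position} falls inside a locus primer region")
        if s.favorable_base == s.wild_type_base:
            bad("site_alleles", f"site {s.site_id}: favorable and wild-type base are identical")
        for lbl, b in (("favorable", s.favorable_base), ("wild-type", s.wild_type_base)):
            if b not in "ACGT":
                bad("site_alleles", f"site {s.site_id}: {lbl} base {b!r} not one of A/C/G/T")
        if 1 <= s.position <= L and m.reference_amplicon[s.position - 1] != s.favorable_base:
            bad("reference_favorable",
                f"site {s.site_id}: reference amplicon carries "
                f"{m.reference_amplicon[s.position - 1]!r} at position {s.position}, "
                f"expected the favorable base {s.favorable_base!r}")
    return out


def validate_sample_sheet(samples: Sequence[BarcodeRecord],
                          max_barcode_mismatch: int = 1,
                          known_markers: Optional[Sequence[str]] = None) -> List[Finding]:
    out: List[Finding] = []
    seen_ids: set = set()
    for s in samples:
        if s.sample_id in seen_ids:
            out.append(Finding(s.sample_id, "duplicate_sample", "duplicate sample_id"))
        seen_ids.add(s.sample_id)
        if not is_dna(s.barcode):
            out.append(Finding(s.sample_id, "barcode_alphabet", "barcode is not DNA over ACGT"))
        elif not (BARCODE_MIN_LEN <= len(s.barcode) <= BARCODE_MAX_LEN):
            out.append(Finding(
                s.sample_id, "barcode_length",
                f"barcode length {len(s.barcode)} outside "
                f"[{BARCODE_MIN_LEN}, {BARCODE_MAX_LEN}]"))
        if known_markers is not None:
            for mid in (*s.is_positive_control_for, *s.is_negative_control_for):
                if mid not in known_markers:
                    out.append(Finding(s.sample_id, "unknown_control_marker",
                                       f"control annotation references unknown marker {mid!r}"))
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if not (is_dna(a.barcode) and is_dna(b.barcode)):
                continue
            d = prefix_distance(a.barcode, b.barcode)
            if d <= max_barcode_mismatch:
                out.append(Finding(
                    f"{a.sample_id}/{b.sample_id}", "barcode_collision",
                    f"barcodes {a.barcode} and {b.barcode} are within "
                    f"{max_barcode_mismatch} mismatches (distance {d})"))
    return out


def validate_panel(panel: Panel,
                   max_barcode_mismatch: int = 1,
                   max_primer_mismatch: int = 2) -> List[Finding]:
    """Check every panel invariant; returns one Finding per violation.

    Never mutates or raises — an empty list means the panel is valid and
    every downstream stage will accept it.
    """
    out: List[Finding] = []
    ids = [m.marker_id for m in panel.markers]
    for mid in sorted({i for i in ids if ids.count(i) > 1}):
        out.append(Finding(mid, "duplicate_marker", "duplicate marker_id"))
    for m in panel.markers:
        out.extend(_validate_marker(m))
    # forward primers must stay distinguishable as read prefixes at the
    # marker-assignment tolerance (the shared M13 tail contributes nothing).
    for i, a in enumerate(panel.markers):
        for b in panel.markers[i + 1:]:
            if not (is_dna(a.forward_primer) and is_dna(b.forward_primer)):
                continue
            d = prefix_distance(a.forward_primer, b.forward_primer)
            if d <= max_primer_mismatch:
                out.append(Finding(
                    f"{a.marker_id}/{b.marker_id}", "ambiguous_primer_pair",
                    f"forward primers are within {max_primer_mismatch} mismatches "
                    f"over their shared prefix (distance {d})"))
    out.extend(validate_sample_sheet(panel.samples, max_barcode_mismatch,
                                     known_markers=ids))
    return out


# ---------------------------------------------------------------------------
# file I/O

def _parse_sites(spec: str, marker_id: str) -> tuple:
    """Parse a "pos:fav:wt[,pos:fav:wt...]" site list; site ids become SNP<pos>."""
    sites = []
    spec = (spec or "").strip()
    if not spec:
        return ()
    for part in spec.split(","):
        bits = part.strip().split(":")
        if len(bits) != 3:
            raise PanelFormatError(
                f"marker {marker_id!r}: site {part!r} is not a pos:fav:wt triplet")
        pos_s, fav, wt = bits
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise PanelFormatError(
                f"marker {marker_id!r}: site position {pos_s!r} is not an integer") from exc
        sites.append(VariantSite(site_id=f"SNP{pos}", position=pos,
                                 favorable_base=fav.upper(), wild_type_base=wt.upper()))
    return tuple(sites)


def _format_sites(sites: Sequence[VariantSite]) -> str:
    return ",".join(f"{s.position}:{s.favorable_base}:{s.wild_type_base}" for s in sites)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise PanelFormatError(f"{what} is missing required column {col!r}")


def load_panel(panel_tsv_path, reference_fasta_path,
               sample_sheet_path=None,
               adapters: Optional[AdapterSet] = None,
               max_barcode_mismatch: int = 1,
               max_primer_mismatch: int = 2) -> Panel:
    """Load and validate a marker panel (TSV + FASTA, optional sample sheet).

    Raises PanelFormatError for structural problems and PanelValidationError
    (listing every finding) for invariant violations.
    """
    df = pd.read_csv(panel_tsv_path, sep="\t", dtype=str).fillna("")
    _require_columns(df, PANEL_COLUMNS, "panel TSV")
    refs: Dict[str, str] = {rec.id: str(rec.seq).upper()
                            for rec in SeqIO.parse(str(reference_fasta_path), "fasta")}
    markers = []
    for row in df.itertuples(index=False):
        mid = str(row.marker_id)
        if mid not in refs:
            raise PanelFormatError(f"reference FASTA has no record for marker {mid!r}")
        sites = _parse_sites(str(row.sites), mid)
        trait = str(getattr(row, "trait", "") or "")
        if trait:
            sites = tuple(replace(s, trait_label=trait) for s in sites)
        markers.append(MarkerDefinition(
            marker_id=mid,
            forward_primer=str(row.fwd_primer).upper(),
            reverse_primer=str(row.rev_primer).upper(),
            reference_amplicon=refs[mid],
            sites=sites,
            mode=str(row.mode),
            specificity=str(row.specificity),
        ))
    samples: List[BarcodeRecord] = []
    if sample_sheet_path is not None:
        samples = load_sample_sheet(sample_sheet_path,
                                    max_barcode_mismatch=max_barcode_mismatch)
    panel = Panel(markers=markers, samples=samples, adapters=adapters or AdapterSet())
    findings = validate_panel(panel, max_barcode_mismatch, max_primer_mismatch)
    if findings:
        raise PanelValidationError(
            "panel failed validation:\n" + "\n".join(str(f) for f in findings))
    return panel


def _split_list(value: str) -> tuple:
    value = (value or "").strip()
    return tuple(v.strip() for v in value.split(",") if v.strip()) if value else ()


def load_sample_sheet(tsv_path, max_barcode_mismatch: int = 1) -> List[BarcodeRecord]:
    """Load the sample sheet and check barcode separability at the demux tolerance."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["sample_id", "barcode"], "sample sheet TSV")
    samples = [BarcodeRecord(
        sample_id=str(r.sample_id),
        barcode=str(r.barcode).upper(),
        is_positive_control_for=_split_list(str(getattr(r, "pos_control_for", ""))),
        is_negative_control_for=_split_list(str(getattr(r, "neg_control_for", ""))),
    ) for r in df.itertuples(index=False)]
    findings = validate_sample_sheet(samples, max_barcode_mismatch)
    if findings:
        raise PanelValidationError(
            "sample sheet failed validation:\n" + "\n".join(str(f) for f in findings))
    return samples


def write_panel(panel: Panel, tsv_path, fasta_path) -> None:
    rows = []
    for m in panel.markers:
        rows.append({
            "marker_id": m.marker_id,
            "fwd_primer": m.forward_primer,
            "rev_primer": m.reverse_primer,
            "mode": m.mode,
            "specificity": m.specificity,
            "sites": _format_sites(m.sites),
            "trait": m.sites[0].trait_label if m.sites else "",
        })
    pd.DataFrame(rows, columns=PANEL_COLUMNS + ["trait"]).to_csv(tsv_path, sep="\t", index=False)
    records = [SeqRecord(Seq(m.reference_amplicon), id=m.marker_id, description="")
               for m in panel.markers]
    SeqIO.write(records, str(fasta_path), "fasta")


def write_sample_sheet(samples: Sequence[BarcodeRecord], tsv_path) -> None:
    rows = [{
        "sample_id": s.sample_id,
        "barcode": s.barcode,
        "pos_control_for": ",".join(s.is_positive_control_for),
        "neg_control_for": ",".join(s.is_negative_control_for),
    } for s in samples]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
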