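"""Synthetic multiplexed amplicon reads with known ground truth.

The simulator emulates the two-step fusion-PCR library on a hexaploid
background: for every (sample, marker) pair it draws reads uniformly from
the 2c allele-resolved amplicon templates of the c co-amplified genome
copies (c = 1, 2 or 3 by primer genome-specificity), wraps each template in
the barcode | M13 | amplicon | P1/B read structure, applies iid
substitution errors, and pools everything with optional unstructured
contaminant reads. Under equal template amplification the expected
favorable-allele read fraction is purely combinatorial:

    E[% favorable] = 100 * (favorable allele copies) / (2c)

which for one to three genomes gives 100/50/0, 50/25/0 and 33.3/16.7/0 for
a target genome that is hom-favorable / het / hom-wild — the classic
dilution of an allele signal by wild-type homoeologs. The model returns the
exact rational value; printed tables traditionally truncate (16, 33), so a
floor helper is provided for comparison.

Per-genome diploid genotypes are written AA / AT / TT in the generic sense:
A = favorable allele, T = wild-type allele, whatever the actual bases are.
A genome copy's genotype applies jointly to all sites of a marker (one
favorable and one wild haplotype); independent per-site phasing is not
modeled. Non-target homoeolog copies carry wild-type bases.

All randomness flows from a single integer seed; identical scenarios yield
byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .dna import DNA_BASES, random_dna, revcomp
from .panel import (AMPLICON_MAX_LEN, AMPLICON_MIN_LEN, BarcodeRecord,
                    MarkerDefinition, Panel, VariantSite, validate_panel)
from .primers import read_sequence

GENOTYPES = ("AA", "AT", "TT")
_FAVORABLE_DOSE = {"AA": 2, "AT": 1, "TT": 0}

#: FASTQ placeholder quality (constant Q30)
_QUAL_CHAR = chr(30 + 33)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def expected_allele_fraction(genotypes_per_genome: Sequence[str]) -> float:
    """Expected % favorable-allele reads under equal template amplification.

    ``genotypes_per_genome`` lists the diploid genotype (AA/AT/TT) of each
    co-amplified genome copy; the result is 100 x favorable alleles / (2c),
    exact (e.g. 100/6 = 16.666... for [AT, TT, TT]).
    """
    return float(exact_allele_fraction(genotypes_per_genome))


def exact_allele_fraction(genotypes_per_genome: Sequence[str]) -> Fraction:
    if not genotypes_per_genome:
        raise ValueError("at least one co-amplified genome is required")
    if len(genotypes_per_genome) > 3:
        raise ValueError("at most three co-amplified genomes are modeled")
    dose = 0
    for g in genotypes_per_genome:
        if g not in _FAVORABLE_DOSE:
            raise ValueError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")
        dose += _FAVORABLE_DOSE[g]
    return Fraction(100 * dose, 2 * len(genotypes_per_genome))


def floor_allele_fraction(genotypes_per_genome: Sequence[str]) -> int:
    """Exact expected fraction floor-rounded to an integer, as printed tables do."""
    return math.floor(exact_allele_fraction(genotypes_per_genome))


@dataclass(frozen=True)
class GenomeModel:
    """Per-genome diploid genotypes for one (sample, marker) pair."""

    genotypes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("GenomeModel needs at least one genome copy")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r}")

    @property
    def expected_fraction(self) -> float:
        return expected_allele_fraction(self.genotypes)


@dataclass
class SimScenario:
    """Everything needed to generate one synthetic run deterministically."""

    panel: Panel
    truth: Dict[Tuple[str, str], GenomeModel]
    reads_per_marker: Union[float, Dict[str, float]] = 889.0
    depth_dispersion: Optional[float] = 10.0  # NB size; None -> constant depth
    substitution_error_rate: float = 0.005
    null_samples: Set[Tuple[str, str]] = field(default_factory=set)
    contaminant_fraction: float = 0.03
    seed: int = 0
    het_calling_expected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_error_rate <= 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1]")
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        means = (self.reads_per_marker.values()
                 if isinstance(self.reads_per_marker, dict) else [self.reads_per_marker])
        if any(m < 0 for m in means):
            raise ValueError("mean depth must be >= 0")


@dataclass
class SimResult:
    """Simulation output: the truth table and exact per-pair read accounting."""

    truth_table: pd.DataFrame
    emitted: pd.DataFrame  # sample_id, marker_id, n_reads actually written
    n_contaminants: int
    fastq_path: Optional[Path]

    @property
    def total_reads(self) -> int:
        return int(self.emitted["n_reads"].sum()) + self.n_contaminants


def _marker_mean(scenario: SimScenario, marker_id: str) -> float:
    if isinstance(scenario.reads_per_marker, dict):
        return float(scenario.reads_per_marker[marker_id])
    return float(scenario.reads_per_marker)


def _haplotype_templates(marker: MarkerDefinition, model: GenomeModel) -> List[str]:
    """The 2c allele-resolved amplicon templates for one genome model.

    The reference amplicon carries the favorable base at every site; the
    wild haplotype swaps each site to its wild-type base. Homoeolog copies
    differ from the target only at the annotated sites (divergence elsewhere
    is not modeled).
    """
    fav = marker.reference_amplicon
    wild_chars = list(fav)
    for s in marker.sites:
        wild_chars[s.position - 1] = s.wild_type_base
    wild = "".join(wild_chars)
    haplos = {"A": fav, "T": wild}
    templates: List[str] = []
    for g in model.genotypes:
        templates.extend(haplos[a] for a in g)
    return templates


def _expected_call(marker: MarkerDefinition, model: Optional[GenomeModel],
                   is_null: bool, het_expected: bool) -> str:
    if marker.mode == "dominant_null":
        return "null_allele_putative" if is_null else "homozygous_positive"
    target = model.genotypes[0]
    if target == "AA":
        return "homozygous_positive"
    if target == "AT" and het_expected:
        return "heterozygous"
    return "homozygous_negative"


def build_truth_table(scenario: SimScenario) -> pd.DataFrame:
    """Per (sample, marker, site) expected fraction and expected categorical call."""
    rows = []
    for (sample_id, marker_id), model in scenario.truth.items():
        marker = scenario.panel.marker(marker_id)
        is_null = (sample_id, marker_id) in scenario.null_samples
        call = _expected_call(marker, model, is_null, scenario.het_calling_expected)
        frac = float("nan") if is_null else model.expected_fraction
        site_ids = [s.site_id for s in marker.sites] or ["amplicon"]
        for sid in site_ids:
            rows.append({"sample_id": sample_id, "marker_id": marker_id,
                         "site_id": sid, "expected_fraction": frac,
                         "expected_call": call})
    df = pd.DataFrame(rows, columns=["sample_id", "marker_id", "site_id",
                                     "expected_fraction", "expected_call"])
    return df.sort_values(["sample_id", "marker_id", "site_id"]).reset_index(drop=True)


def _mutate_reads(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """iid substitutions on a (n_reads, read_len) base-code matrix (codes 0-3)."""
    if rate <= 0 or mat.size == 0:
        return mat
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return mat


def simulate_reads(scenario: SimScenario, fastq_path=None) -> SimResult:
    """Generate the run's FASTQ (4-line, constant Q30) and its truth tables.

    Read order is shuffled deterministically; contaminant reads are uniform
    random DNA with no valid barcode/primer structure.
    """
    rng = np.random.default_rng(scenario.seed)
    panel = scenario.panel
    barcode_of = {s.sample_id: s.barcode for s in panel.samples}
    adapters = panel.adapters

    all_reads: List[Tuple[str, str]] = []
    emitted_rows = []
    for (sample_id, marker_id) in sorted(scenario.truth):
        model = scenario.truth[(sample_id, marker_id)]
        marker = panel.marker(marker_id)
        if (sample_id, marker_id) in scenario.null_samples:
            emitted_rows.append({"sample_id": sample_id, "marker_id": marker_id,
                                 "n_reads": 0})
            continue
        mean = _marker_mean(scenario, marker_id)
        if scenario.depth_dispersion is None:
            count = int(round(mean))
        else:
            size = float(scenario.depth_dispersion)
            count = int(rng.negative_binomial(size, size / (size + mean))) if mean > 0 else 0
        emitted_rows.append({"sample_id": sample_id, "marker_id": marker_id,
                             "n_reads": count})
        if count == 0:
            continue
        templates = _haplotype_templates(marker, model)
        full = [read_sequence(marker, barcode_of[sample_id], adapters, amplicon=t)
                for t in templates]
        codes = np.stack([_CODE_OF[np.frombuffer(t.encode(), dtype=np.uint8)]
                          for t in full])
        draws = rng.integers(0, len(templates), size=count)
        mat = _mutate_reads(codes[draws].copy(), scenario.substitution_error_rate, rng)
        block = _BASE_BYTES[mat].tobytes()
        L = mat.shape[1]
        for k in range(count):
            all_reads.append((f"sim:{sample_id}:{marker_id}:{k}",
                              block[k * L:(k + 1) * L].decode()))

    n_structured = len(all_reads)
    f = scenario.contaminant_fraction
    n_contam = int(round(n_structured * f / (1.0 - f))) if f > 0 else 0
    for k in range(n_contam):
        length = int(rng.integers(AMPLICON_MIN_LEN, AMPLICON_MAX_LEN + 60))
        all_reads.append((f"contam:{k}", random_dna(rng, length)))

    order = rng.permutation(len(all_reads))
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for idx in order:
                rid, seq = all_reads[idx]
                fh.write(f"@{rid}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")

    emitted = pd.DataFrame(emitted_rows,
                           columns=["sample_id", "marker_id", "n_reads"])
    return SimResult(truth_table=build_truth_table(scenario), emitted=emitted,
                     n_contaminants=n_contam,
                     fastq_path=Path(fastq_path) if fastq_path is not None else None)


# ---------------------------------------------------------------------------
# default panel / scenario builders

def _random_barcodes(rng: np.random.Generator, n: int, min_distance: int = 3) -> List[str]:
    from .dna import prefix_distance

    barcodes: List[str] = []
    while len(barcodes) < n:
        cand = random_dna(rng, int(rng.integers(10, 13)))
        if all(prefix_distance(cand, b) >= min_distance for b in barcodes):
            barcodes.append(cand)
    return barcodes


def make_default_panel(n_markers: int, seed: int, n_samples: int = 24,
                       dominant_every: int = 9,
                       sites_per_marker: Tuple[int, int] = (1, 3)) -> Panel:
    """A random but valid panel: primers, amplicons, sites, barcoded samples.

    Specificity cycles genome_specific -> semi_specific -> non_specific;
    every ``dominant_every``-th marker is a dominant presence/absence marker
    (the panel this emulates carried 3 dominant markers among 27).
    Deterministic under ``seed``.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    markers: List[MarkerDefinition] = []
    fwd_primers: List[str] = []
    from .dna import prefix_distance

    for i in range(n_markers):
        while True:
            fwd = random_dna(rng, int(rng.integers(17, 22)))
            if all(prefix_distance(fwd, p) >= 3 for p in fwd_primers):
                break
        fwd_primers.append(fwd)
        rev = random_dna(rng, int(rng.integers(17, 22)))
        total = int(rng.integers(AMPLICON_MIN_LEN, AMPLICON_MAX_LEN + 1))
        core_len = max(20, total - len(fwd) - len(rev))
        core = random_dna(rng, core_len)
        amplicon = fwd + core + revcomp(rev)
        n_sites = int(rng.integers(sites_per_marker[0], sites_per_marker[1] + 1))
        lo, hi = len(fwd) + 1, len(amplicon) - len(rev)
        positions = sorted(int(p) for p in
                           rng.choice(np.arange(lo, hi + 1), size=n_sites, replace=False))
        sites = []
        for pos in positions:
            fav = amplicon[pos - 1]
            wt = rng.choice([b for b in DNA_BASES if b != fav])
            sites.append(VariantSite(site_id=f"SNP{pos}", position=pos,
                                     favorable_base=fav, wild_type_base=str(wt)))
        mode = "dominant_null" if dominant_every and (i + 1) % dominant_every == 0 \
            else "codominant"
        specificity = ("genome_specific", "semi_specific", "non_specific")[i % 3]
        markers.append(MarkerDefinition(
            marker_id=f"M{i + 1:03d}", forward_primer=fwd, reverse_primer=rev,
            reference_amplicon=amplicon, sites=tuple(sites), mode=mode,
            specificity=specificity))

    samples = [BarcodeRecord(sample_id=f"S{j + 1:02d}", barcode=bc)
               for j, bc in enumerate(_random_barcodes(rng, n_samples))]
    panel = Panel(markers=markers, samples=samples)
    findings = validate_panel(panel)
    if findings:  # pragma: no cover - generator guarantees validity
        raise AssertionError("generated panel failed validation: "
                             + "; ".join(map(str, findings)))
    return panel


def make_default_scenario(panel: Panel, seed: int,
                          reads_per_marker: Union[float, Dict[str, float]] = 889.0,
                          depth_dispersion: Optional[float] = 10.0,
                          substitution_error_rate: float = 0.005,
                          contaminant_fraction: float = 0.03,
                          favorable_probability: float = 0.5) -> SimScenario:
    """A validation-run scenario over a panel of known homozygous samples.

    Every sample is homozygous at every marker (favorable with probability
    ``favorable_probability``, at least one favorable sample per marker).
    All known hom-favorable samples are flagged as positive-control
    replicates for their markers — the design of a marker-validation run on
    characterized germplasm, where the in-run control minimum then anchors
    the homozygous-positive cutoff at the low edge of the positive class.
    Dominant-marker wild samples produce no reads at all (null alleles).
    """
    rng = np.random.default_rng(seed)
    truth: Dict[Tuple[str, str], GenomeModel] = {}
    null_samples: Set[Tuple[str, str]] = set()
    pos_controls: Dict[str, List[str]] = {s.sample_id: [] for s in panel.samples}
    neg_controls: Dict[str, List[str]] = {s.sample_id: [] for s in panel.samples}

    for marker in panel.markers:
        c = marker.copies_coamplified
        fav_flags = rng.random(len(panel.samples)) < favorable_probability
        if not fav_flags.any():
            fav_flags[int(rng.integers(0, len(panel.samples)))] = True
        first_negative = True
        for flag, sample in zip(fav_flags, panel.samples):
            key = (sample.sample_id, marker.marker_id)
            if flag:
                truth[key] = GenomeModel(("AA",) + ("TT",) * (c - 1))
                pos_controls[sample.sample_id].append(marker.marker_id)
            else:
                truth[key] = GenomeModel(("TT",) * c)
                if marker.mode == "dominant_null":
                    null_samples.add(key)
                if first_negative:
                    neg_controls[sample.sample_id].append(marker.marker_id)
                    first_negative = False

    annotated = [replace(s,
                         is_positive_control_for=tuple(pos_controls[s.sample_id]),
                         is_negative_control_for=tuple(neg_controls[s.sample_id]))
                 for s in panel.samples]
    panel_with_controls = Panel(markers=panel.markers, samples=annotated,
                                adapters=panel.adapters)
    return SimScenario(panel=panel_with_controls, truth=truth,
                       reads_per_marker=reads_per_marker,
                       depth_dispersion=depth_dispersion,
                       substitution_error_rate=substitution_error_rate,
                       null_samples=null_samples,
                       contaminant_fraction=contaminant_fraction,
                       seed=seed)


def single_marker_scenario(genotypes: Sequence[str], depth: int, seed: int,
                           substitution_error_rate: float = 0.0,
                           n_sites: int = 1) -> SimScenario:
    """Minimal one-sample, one-marker scenario for calibration experiments.

    The marker's genome specificity follows from ``len(genotypes)`` (1-3
    co-amplified genomes); depth is constant (no dispersion), contaminants
    are off, and the single sample is its own positive control.
    """
    c = len(genotypes)
    specificity = {1: "genome_specific", 2: "semi_specific", 3: "non_specific"}[c]
    panel = make_default_panel(1, seed=seed, n_samples=1, dominant_every=0,
                               sites_per_marker=(n_sites, n_sites))
    marker = replace(panel.markers[0], specificity=specificity)
    sample = replace(panel.samples[0],
                     is_positive_control_for=(marker.marker_id,))
    panel = Panel(markers=[marker], samples=[sample], adapters=panel.adapters)
    truth = {(sample.sample_id, marker.marker_id): GenomeModel(tuple(genotypes))}
    return SimScenario(panel=panel, truth=truth, reads_per_marker=float(depth),
                       depth_dispersion=None,
                       substitution_error_rate=substitution_error_rate,
                       contaminant_fraction=0.0, seed=seed)
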