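"""Allele counting and control-anchored genotype calling.

The final pipeline stage tabulates, per (sample, marker, site), how many
accepted aligned reads show A, C, G, T or N (gap/absence) at the site, and
turns those pileups into categorical genotype calls:

* percent favorable = 100 * n_favorable / total, computed at full precision
  (displayed to one decimal; never silently 0 when the total is 0);
* the homozygous-positive cutoff for each (marker, site) is the minimum
  percent favorable observed among that run's qualifying positive-control
  replicates — controls must be in the run, a universal cutoff does not
  exist because the percentage varies with primer genome specificity and
  between runs;
* a sample at or above the cutoff is homozygous positive, below it
  homozygous negative ("equal to or greater" — ties pass);
* fewer than ``min_reads_per_allele`` (default 10) accepted reads at a site
  is no call: too few reads make the read-fraction estimate unreliable;
* dominant presence/absence markers never yield homozygous negative: reads
  present at depth means positive, zero reads is a putative null allele
  (flagged with caution — indistinguishable from PCR failure), and a
  sub-threshold trickle is no call;
* heterozygote calling is off by default: in a polyploid the het/hom
  separation is compressed (25 vs 50%, 16.7 vs 33.3%), so an explicit
  synthetic-heterozygote control band must be supplied to enable it.

Concordance against an external call table (e.g. a uniplex fluorescence
assay) is the proportion of matched calls among compared samples; no-call
entries are excluded from the denominator by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .align import PRESENCE_SITE_ID, SiteObservation
from .panel import Panel, VariantSite

BASES_N = ("A", "C", "G", "T", "N")
COUNT_COLUMNS = ["n_A", "n_C", "n_G", "n_T", "n_N"]

CALL_HOM_POS = "homozygous_positive"
CALL_HOM_NEG = "homozygous_negative"
CALL_HET = "heterozygous"
CALL_NO_DEPTH = "no_call_low_depth"
CALL_NO_CONTROL = "no_call_no_control"
CALL_NULL = "null_allele_putative"

NO_CALL_PREFIX = "no_call"


@dataclass(frozen=True)
class CallingConfig:
    min_reads_per_allele: int = 10
    het_calling_enabled: bool = False
    het_band: Optional[Tuple[float, float]] = None  # percent interval, used only when enabled

    def __post_init__(self) -> None:
        if self.min_reads_per_allele < 1:
            raise ValueError("min_reads_per_allele must be >= 1")
        if self.het_calling_enabled and self.het_band is None:
            raise ValueError("heterozygote calling requires an explicit het_band "
                             "(derive it from a synthetic heterozygote control)")


@dataclass(frozen=True)
class ControlCutoff:
    marker_id: str
    site_id: str
    cutoff_percent: float
    source_samples: Tuple[str, ...]  # qualifying positive-control replicates


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: Optional[str]
    marker_id: Optional[str]
    site_id: Optional[str]
    depth: int
    percent_favorable: Optional[float]  # None (undefined) when depth == 0
    call: str
    caution_flag: bool = False
    reason: str = ""


def count_alleles(observations: Iterable[SiteObservation],
                  panel: Optional[Panel] = None,
                  sample_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tabulate per-(sample, marker, site) base counts from site observations.

    When the panel (and optionally a sample list) is given, every expected
    key appears in the table even with zero observations, so the null-allele
    logic downstream can see zero-read pairs.
    """
    counts: Dict[Tuple[str, str, str], List[int]] = {}
    base_idx = {b: i for i, b in enumerate(BASES_N)}
    if panel is not None:
        samples = list(sample_ids) if sample_ids is not None else panel.sample_ids
        for s in samples:
            for m in panel.markers:
                for site_id in ([site.site_id for site in m.sites] or [PRESENCE_SITE_ID]):
                    counts[(s, m.marker_id, site_id)] = [0] * 5
    for obs in observations:
        key = (obs.sample_id, obs.marker_id, obs.site_id)
        row = counts.get(key)
        if row is None:
            row = counts[key] = [0] * 5
        row[base_idx[obs.observed]] += 1
    records = [{"sample_id": s, "marker_id": m, "site_id": site,
                **dict(zip(COUNT_COLUMNS, row)), "total": sum(row)}
               for (s, m, site), row in counts.items()]
    df = pd.DataFrame(records, columns=["sample_id", "marker_id", "site_id",
                                        *COUNT_COLUMNS, "total"])
    return df.sort_values(["sample_id", "marker_id", "site_id"]).reset_index(drop=True)


def percent_favorable(counts: Mapping[str, int], favorable_base: str) -> Optional[float]:
    """100 x favorable count / total accepted reads; None (undefined) at total 0."""
    total = sum(int(counts[c]) for c in COUNT_COLUMNS) if "total" not in counts \
        else int(counts["total"])
    if total == 0:
        return None
    return 100.0 * int(counts[f"n_{favorable_base}"]) / total


def _site_lookup(panel: Panel) -> Dict[Tuple[str, str], VariantSite]:
    return {(m.marker_id, s.site_id): s for m in panel.markers for s in m.sites}


def derive_cutoffs(count_table: pd.DataFrame, samples,
                   panel: Panel,
                   config: CallingConfig = CallingConfig()) -> List[ControlCutoff]:
    """Homozygous-positive cutoffs from this run's positive controls.

    For each (marker, site): the minimum percent favorable among positive-
    control replicates with at least ``min_reads_per_allele`` accepted
    reads. A single qualifying control degenerates to its own value; no
    qualifying control means no cutoff (downstream codominant calls become
    no-call — controls must be included in each run).
    """
    controls_for: Dict[str, List[str]] = {}
    for rec in samples:
        for mid in rec.is_positive_control_for:
            controls_for.setdefault(mid, []).append(rec.sample_id)
    sites = _site_lookup(panel)
    indexed = count_table.set_index(["sample_id", "marker_id", "site_id"])
    out: List[ControlCutoff] = []
    for (marker_id, site_id), site in sorted(sites.items()):
        best: List[Tuple[str, float]] = []
        for sample_id in controls_for.get(marker_id, ()):
            try:
                row = indexed.loc[(sample_id, marker_id, site_id)]
            except KeyError:
                continue
            if int(row["total"]) < config.min_reads_per_allele:
                continue
            pct = percent_favorable(row, site.favorable_base)
            if pct is not None:
                best.append((sample_id, pct))
        if best:
            cutoff = min(p for _, p in best)
            out.append(ControlCutoff(marker_id=marker_id, site_id=site_id,
                                     cutoff_percent=cutoff,
                                     source_samples=tuple(s for s, _ in best)))
    return out


def cutoff_frame(cutoffs: Sequence[ControlCutoff]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"marker_id": c.marker_id, "site_id": c.site_id,
          "cutoff_percent": c.cutoff_percent,
          "control_samples": ",".join(c.source_samples)} for c in cutoffs],
        columns=["marker_id", "site_id", "cutoff_percent", "control_samples"])


def call_genotype(counts: Mapping[str, int], site: Optional[VariantSite],
                  cutoff: Optional[float],
                  config: CallingConfig = CallingConfig(),
                  marker_mode: str = "codominant",
                  sample_id: Optional[str] = None,
                  marker_id: Optional[str] = None) -> GenotypeCall:
    """Apply the calling rules to one (sample, marker, site) pileup.

    The rule set is total and mutually exclusive; see the module docstring.
    """
    total = sum(int(counts[c]) for c in COUNT_COLUMNS) if "total" not in counts \
        else int(counts["total"])
    site_id = site.site_id if site is not None else PRESENCE_SITE_ID
    pct = percent_favorable(counts, site.favorable_base) if site is not None else None

    if marker_mode == "dominant_null":
        if total == 0:
            return GenotypeCall(sample_id, marker_id, site_id, 0, None, CALL_NULL,
                                caution_flag=True,
                                reason="zero reads: null allele or PCR failure")
        if total < config.min_reads_per_allele:
            return GenotypeCall(sample_id, marker_id, site_id, total, pct,
                                CALL_NO_DEPTH,
                                reason=f"depth {total} < {config.min_reads_per_allele}")
        return GenotypeCall(sample_id, marker_id, site_id, total, pct, CALL_HOM_POS,
                            reason="amplicon present")

    if total < config.min_reads_per_allele:
        return GenotypeCall(sample_id, marker_id, site_id, total,
                            pct, CALL_NO_DEPTH,
                            reason=f"depth {total} < {config.min_reads_per_allele}")
    if cutoff is None:
        return GenotypeCall(sample_id, marker_id, site_id, total, pct,
                            CALL_NO_CONTROL,
                            reason="no qualifying in-run positive control")
    if config.het_calling_enabled and config.het_band is not None \
            and config.het_band[0] <= pct <= config.het_band[1]:
        return GenotypeCall(sample_id, marker_id, site_id, total, pct, CALL_HET,
                            reason="within synthetic-het control band")
    if pct >= cutoff:
        return GenotypeCall(sample_id, marker_id, site_id, total, pct, CALL_HOM_POS)
    return GenotypeCall(sample_id, marker_id, site_id, total, pct, CALL_HOM_NEG)


def call_genotypes(count_table: pd.DataFrame, panel: Panel,
                   cutoffs: Sequence[ControlCutoff],
                   config: CallingConfig = CallingConfig()) -> pd.DataFrame:
    """Call every row of the count table; returns the genotype call table."""
    cutoff_of = {(c.marker_id, c.site_id): c.cutoff_percent for c in cutoffs}
    sites = _site_lookup(panel)
    mode_of = {m.marker_id: m.mode for m in panel.markers}
    rows = []
    for rec in count_table.to_dict("records"):
        key = (rec["marker_id"], rec["site_id"])
        call = call_genotype(rec, sites.get(key), cutoff_of.get(key), config,
                             marker_mode=mode_of[rec["marker_id"]],
                             sample_id=rec["sample_id"], marker_id=rec["marker_id"])
        rows.append({
            "sample_id": call.sample_id, "marker_id": call.marker_id,
            "site_id": call.site_id, "depth": call.depth,
            "percent_favorable": (round(call.percent_favorable, 1)
                                  if call.percent_favorable is not None else None),
            "call": call.call, "caution_flag": call.caution_flag,
            "reason": call.reason,
        })
    return pd.DataFrame(rows, columns=["sample_id", "marker_id", "site_id", "depth",
                                       "percent_favorable", "call", "caution_flag",
                                       "reason"])


def is_confident(call: str) -> bool:
    return not str(call).startswith(NO_CALL_PREFIX)


def call_rate(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-marker percent of samples confidently scored (all sites called)."""
    confident = calls.assign(ok=calls["call"].map(is_confident))
    per_sample = confident.groupby(["marker_id", "sample_id"])["ok"].all().reset_index()
    rate = per_sample.groupby("marker_id")["ok"].mean().mul(100.0)
    return rate.rename("call_rate_percent").reset_index()


@dataclass(frozen=True)
class ConcordanceResult:
    overall: Optional[float]  # proportion in [0, 1]; None when nothing compared
    per_marker: pd.DataFrame  # marker_id, n_compared, n_matched, concordance
    n_compared: int


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                include_no_call: bool = False) -> ConcordanceResult:
    """Proportion of matched calls between two identically keyed call tables.

    Tables join on their shared key columns among (sample_id, marker_id,
    site_id). By default any pair where either side is a no-call is excluded
    from the denominator (only scored genotypes are compared); with
    ``include_no_call`` pairs are compared literally, so a no-call against a
    scored call counts as a mismatch.
    """
    keys = [k for k in ("sample_id", "marker_id", "site_id")
            if k in calls_a.columns and k in calls_b.columns]
    if not keys:
        raise ValueError("call tables share no key columns")
    merged = calls_a[keys + ["call"]].merge(
        calls_b[keys + ["call"]], on=keys, suffixes=("_a", "_b"))
    if not include_no_call:
        merged = merged[merged["call_a"].map(is_confident)
                        & merged["call_b"].map(is_confident)]
    if merged.empty:
        warnings.warn("no comparable calls between the two tables; "
                      "concordance is undefined")
        empty = pd.DataFrame(columns=["marker_id", "n_compared", "n_matched",
                                      "concordance"])
        return ConcordanceResult(overall=None, per_marker=empty, n_compared=0)
    merged = merged.assign(match=merged["call_a"] == merged["call_b"])
    if "marker_id" in keys:
        grp = merged.groupby("marker_id")["match"]
        per_marker = pd.DataFrame({
            "marker_id": grp.count().index,
            "n_compared": grp.count().values,
            "n_matched": grp.sum().values,
        })
        per_marker["concordance"] = per_marker["n_matched"] / per_marker["n_compared"]
    else:
        per_marker = pd.DataFrame(columns=["marker_id", "n_compared", "n_matched",
                                           "concordance"])
    return ConcordanceResult(overall=float(merged["match"].mean()),
                             per_marker=per_marker.reset_index(drop=True),
                             n_compared=int(len(merged)))
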