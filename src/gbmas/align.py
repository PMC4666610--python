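"""Pairwise alignment of sorted reads to their marker's reference amplicon.

Each read reaching this stage is already assigned to a single short (<=200
nt) reference, so a k-mer database search tool is unnecessary: a banded,
affine-gap dynamic program gives the identical information deterministically.
The alignment is global in the reference (every reference column is either
matched, mismatched or deleted in the read) and semi-global in the read
(unaligned read prefix/suffix — e.g. a residual 3' adapter — is skipped
free of charge). Identity is matches divided by reference length; reads
under the identity floor are rejected, which is a data outcome, not an
error.

Tie-breaking is fixed so identical inputs always produce identical
alignments: on equal score a diagonal step is preferred over a gap in the
read (reference base deleted), which is preferred over a gap in the
reference (read base inserted); on equal end-point score the smallest read
end index wins.

Scoring convention: a gap of length k costs gap_open + k * gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

NEG_INF = float("-inf")

# state preference on equal score (applied in fill and traceback)
_M, _X, _Y = 0, 1, 2  # diagonal, gap-in-read (consumes ref), gap-in-ref (consumes read)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and acceptance parameters (penalties are magnitudes, >= 0)."""

    match: int = 1
    mismatch: int = 1
    gap_open: int = 2
    gap_extend: int = 1
    min_identity: float = 0.9
    band: int = 10

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if self.band < 1:
            raise ValueError("band width must be >= 1")


@dataclass(frozen=True)
class Alignment:
    """One accepted read-to-reference alignment.

    ``ref_map[j]`` is the 0-based read index aligned to reference column j,
    or None where the read has a gap. ``ops`` is the aligned-region operation
    string over {M: diagonal, D: gap in read, I: gap in reference};
    ``read_start``/``read_end`` delimit the aligned read slice (the rest is
    soft-clipped).
    """

    score: float
    identity: float
    ref_map: Tuple[Optional[int], ...]
    ops: str
    read_start: int
    read_end: int


@dataclass(frozen=True)
class SiteObservation:
    """The base a read shows at one annotated variant position.

    ``observed`` is N when the read has a gap at (or does not cover) the
    site — the pileup treats a deletion and a null identically.
    """

    sample_id: str
    marker_id: str
    site_id: str
    observed: str
    alignment_identity: float


def _diagonal_alignment(read: str, ref: str, params: AlignmentParams,
                        mismatches: int) -> Alignment:
    n = len(ref)
    matches = n - mismatches
    return Alignment(
        score=matches * params.match - mismatches * params.mismatch,
        identity=matches / n,
        ref_map=tuple(range(n)),
        ops="M" * n,
        read_start=0,
        read_end=n,
    )


def align_read(read: str, ref: str,
               params: AlignmentParams = AlignmentParams()) -> Optional[Alignment]:
    """Align a read to a reference amplicon segment; None if identity < floor.

    Banded affine-gap DP as described in the module docstring. A same-length
    pair with at most two mismatches short-circuits to the diagonal
    alignment, which is provably optimal and unique under the default
    scoring (replacing k <= 2 mismatches requires a gap pair costing more
    than the 2k score swing).
    """
    if not read or not ref:
        raise ValueError("align_read requires non-empty sequences")
    m, n = len(read), len(ref)

    if m == n and 2 * (params.gap_open + params.gap_extend) > 4 * params.mismatch:
        mism = 0
        for a, b in zip(read, ref):
            if a != b:
                mism += 1
                if mism > 2:
                    break
        if mism <= 2:
            aln = _diagonal_alignment(read, ref, params, mism)
            return aln if aln.identity >= params.min_identity else None

    band = max(params.band, n - m)  # widen so short reads can still span the reference
    go, ge = params.gap_open, params.gap_extend
    ma, mi = params.match, params.mismatch

    # score matrices, (m+1) x (n+1), band-limited on |i - j| <= band
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    for i in range(0, min(m, band) + 1):
        M[i][0] = 0.0  # free skip of the read prefix

    for i in range(0, m + 1):
        lo = max(1, i - band)
        hi = min(n, i + band)
        Mi, Xi, Yi = M[i], X[i], Y[i]
        if i > 0:
            Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
            ri = read[i - 1]
        for j in range(lo, hi + 1):
            # X: gap in read, consume ref[j-1]
            best = Mi[j - 1] - go - ge
            alt = Xi[j - 1] - ge
            if alt > best:
                best = alt
            alt = Yi[j - 1] - go - ge
            if alt > best:
                best = alt
            Xi[j] = best
            if i > 0:
                # M: align read[i-1] to ref[j-1]
                d = Mp[j - 1]
                if Xp[j - 1] > d:
                    d = Xp[j - 1]
                if Yp[j - 1] > d:
                    d = Yp[j - 1]
                if d > NEG_INF:
                    Mi[j] = d + (ma if ri == ref[j - 1] else -mi)
                # Y: insert read[i-1]
                best = Mp[j] - go - ge
                alt = Yp[j] - ge
                if alt > best:
                    best = alt
                alt = Xp[j] - go - ge
                if alt > best:
                    best = alt
                Yi[j] = best

    # end: any state at j = n, read suffix skipped free; smallest i wins ties
    best_score, best_i, best_state = NEG_INF, -1, -1
    for i in range(max(0, n - band), min(m, n + band) + 1):
        for state, row in ((_M, M), (_X, X), (_Y, Y)):
            s = row[i][n]
            if s > best_score:
                best_score, best_i, best_state = s, i, state
    if best_i < 0:
        return None

    ops_rev: List[str] = []
    ref_map: List[Optional[int]] = [None] * n
    matches = 0
    i, j, state = best_i, n, best_state
    read_end = best_i
    while j > 0:
        if state == _M:
            sub = ma if read[i - 1] == ref[j - 1] else -mi
            ref_map[j - 1] = i - 1
            if read[i - 1] == ref[j - 1]:
                matches += 1
            ops_rev.append("M")
            # predecessor preference M > X > Y
            if i - 1 >= 0 and abs(M[i][j] - (M[i - 1][j - 1] + sub)) < 1e-9 and M[i - 1][j - 1] > NEG_INF:
                state = _M
            elif i - 1 >= 0 and abs(M[i][j] - (X[i - 1][j - 1] + sub)) < 1e-9 and X[i - 1][j - 1] > NEG_INF:
                state = _X
            else:
                state = _Y
            i, j = i - 1, j - 1
        elif state == _X:
            ops_rev.append("D")
            if abs(X[i][j] - (M[i][j - 1] - go - ge)) < 1e-9 and M[i][j - 1] > NEG_INF:
                state = _M
            elif abs(X[i][j] - (X[i][j - 1] - ge)) < 1e-9 and X[i][j - 1] > NEG_INF:
                state = _X
            else:
                state = _Y
            j = j - 1
        else:  # _Y
            ops_rev.append("I")
            if abs(Y[i][j] - (M[i - 1][j] - go - ge)) < 1e-9 and M[i - 1][j] > NEG_INF:
                state = _M
            elif abs(Y[i][j] - (Y[i - 1][j] - ge)) < 1e-9 and Y[i - 1][j] > NEG_INF:
                state = _Y
            else:
                state = _X
            i = i - 1

    identity = matches / n
    if identity < params.min_identity:
        return None
    return Alignment(score=best_score, identity=identity, ref_map=tuple(ref_map),
                     ops="".join(reversed(ops_rev)), read_start=i, read_end=read_end)


#: pseudo-site used to tabulate presence depth for markers without annotated sites
PRESENCE_SITE_ID = "amplicon"


def observe_sites(sorted_read, marker,
                  params: AlignmentParams = AlignmentParams()) -> List[SiteObservation]:
    """Extract one SiteObservation per annotated variant site from one read.

    The read's insert (prefix segments already trimmed by the sorter) is
    aligned to the reference amplicon minus its forward-primer region, so
    site positions are shifted by the forward primer length. A rejected
    alignment yields no observations. Markers without sites (dominant
    presence/absence markers) yield a single presence observation under the
    pseudo-site ``amplicon``.
    """
    offset = len(marker.forward_primer)
    ref_seg = marker.reference_amplicon[offset:]
    aln = align_read(sorted_read.insert_sequence, ref_seg, params)
    if aln is None:
        return []
    obs: List[SiteObservation] = []
    if not marker.sites:
        return [SiteObservation(sorted_read.sample_id, marker.marker_id,
                                PRESENCE_SITE_ID, "N", aln.identity)]
    read = sorted_read.insert_sequence
    for site in marker.sites:
        j = site.position - 1 - offset
        if j < 0 or j >= len(ref_seg):  # validation forbids this; belt and braces
            continue
        ri = aln.ref_map[j]
        base = read[ri] if ri is not None else "N"
        obs.append(SiteObservation(sorted_read.sample_id, marker.marker_id,
                                   site.site_id, base if base in "ACGT" else "N",
                                   aln.identity))
    return obs
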