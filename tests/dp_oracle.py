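"""Independent full (unbanded) dynamic-programming alignment oracle.

This is a deliberately separate, brute-force implementation of the same
alignment contract the package's banded aligner promises — global in the
reference, free read end-skips, affine gaps (open + k * extend), and the
fixed tie-break order diagonal > gap-in-read > gap-in-reference, smallest
read end index on equal end score. It enumerates the full DP matrix with
explicit predecessor pointers and no band, so agreement with the banded
aligner on pairs whose optimal path stays inside the band is a genuine
cross-check, not a shared code path.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

NEG = float("-inf")
M, X, Y = 0, 1, 2  # diagonal, gap-in-read (consumes ref), gap-in-ref (consumes read)


def full_dp_align(read: str, ref: str, match: int = 1, mismatch: int = 1,
                  gap_open: int = 2, gap_extend: int = 1
                  ) -> Tuple[float, str, Tuple[Optional[int], ...], int, int]:
    """Returns (score, ops, ref_map, read_start, read_end)."""
    m, n = len(read), len(ref)
    go_ge = gap_open + gap_extend

    score = [[[NEG] * 3 for _ in range(n + 1)] for _ in range(m + 1)]
    ptr = [[[-1] * 3 for _ in range(n + 1)] for _ in range(m + 1)]
    for i in range(m + 1):
        score[i][0][M] = 0.0  # free skip of read prefix

    for i in range(m + 1):
        for j in range(1, n + 1):
            # X: ref[j-1] aligned to a gap in the read
            cands = [(score[i][j - 1][M] - go_ge, M),
                     (score[i][j - 1][X] - gap_extend, X),
                     (score[i][j - 1][Y] - go_ge, Y)]
            best, src = cands[0]
            for s, st in cands[1:]:
                if s > best:
                    best, src = s, st
            score[i][j][X], ptr[i][j][X] = best, src
            if i > 0:
                sub = match if read[i - 1] == ref[j - 1] else -mismatch
                cands = [(score[i - 1][j - 1][M], M),
                         (score[i - 1][j - 1][X], X),
                         (score[i - 1][j - 1][Y], Y)]
                best, src = cands[0]
                for s, st in cands[1:]:
                    if s > best:
                        best, src = s, st
                if best > NEG:
                    score[i][j][M], ptr[i][j][M] = best + sub, src
                # Y: read[i-1] inserted relative to the reference
                cands = [(score[i - 1][j][M] - go_ge, M),
                         (score[i - 1][j][Y] - gap_extend, Y),
                         (score[i - 1][j][X] - go_ge, X)]
                best, src = cands[0]
                for s, st in cands[1:]:
                    if s > best:
                        best, src = s, st
                score[i][j][Y], ptr[i][j][Y] = best, src

    best_score, best_i, best_state = NEG, -1, -1
    for i in range(m + 1):
        for state in (M, X, Y):
            if score[i][n][state] > best_score:
                best_score, best_i, best_state = score[i][n][state], i, state

    ops_rev: List[str] = []
    ref_map: List[Optional[int]] = [None] * n
    i, j, state = best_i, n, best_state
    while j > 0:
        nxt = ptr[i][j][state]
        if state == M:
            ref_map[j - 1] = i - 1
            ops_rev.append("M")
            i, j = i - 1, j - 1
        elif state == X:
            ops_rev.append("D")
            j -= 1
        else:
            ops_rev.append("I")
            i -= 1
        state = nxt
    return best_score, "".join(reversed(ops_rev)), tuple(ref_map), i, best_i


def mutate_with_indels(rng, seq: str, n_subs: int, max_indel: int) -> str:
    """Derive a read from a reference with substitutions and <= max_indel-nt indels."""
    bases = "ACGT"
    chars = list(seq)
    for _ in range(n_subs):
        pos = int(rng.integers(0, len(chars)))
        chars[pos] = bases[(bases.index(chars[pos]) + int(rng.integers(1, 4))) % 4]
    if max_indel > 0:
        size = int(rng.integers(1, max_indel + 1))
        pos = int(rng.integers(1, max(2, len(chars) - size)))
        if rng.random() < 0.5:
            del chars[pos:pos + size]
        else:
            ins = [bases[int(b)] for b in rng.integers(0, 4, size)]
            chars[pos:pos] = ins
    return "".join(chars)
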