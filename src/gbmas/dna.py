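"""Small DNA string utilities shared across the package.

Everything operates on plain upper-case strings over {A,C,G,T} (plus N
where noted); sequences are upper-cased once on ingest, never here.
"""

from __future__ import annotations

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: str = DNA_BASES) -> bool:
    return bool(seq) and all(c in alphabet for c in seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def hamming_within(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit: returns limit+1 as soon as it is exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return limit + 1
    return d


def prefix_distance(a: str, b: str) -> int:
    """Hamming distance over the shorter of the two strings (length alignment).

    This is the separation that matters for prefix-based matching: two
    sequences at prefix distance 0 are indistinguishable as read prefixes
    even if their full lengths differ.
    """
    n = min(len(a), len(b))
    return hamming(a[:n], b[:n])


def random_dna(rng, length: int) -> str:
    """Uniform random DNA string from a numpy Generator."""
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))
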