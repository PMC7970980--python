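"""Low-level DNA sequence helpers shared across modules.

All sequences are plain upper-case strings over A/C/G/T (IUPAC ambiguity
codes and gaps are tolerated only where a function says so).  Coordinates
are 0-based, intervals half-open.
"""
from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
_BASE_SET = frozenset(BASES)
# characters accepted in aligned input (IUPAC + gap); used by I/O validation
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

# missing-data characters ignored under pairwise deletion
MISSING = frozenset("-N?.")


def stable_rng(label: str, salt: int = 0) -> np.random.Generator:
    """Deterministic RNG keyed by a string label, independent of any
    user-facing seed.  Used to pin fixture/ancestor sequences."""
    key = zlib.crc32(label.encode("utf-8")) ^ (salt * 0x9E3779B1 & 0xFFFFFFFF)
    return np.random.default_rng(key & 0x7FFFFFFF)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    if length < 0:
        raise ValueError("length must be non-negative")
    return "".join(rng.choice(list(BASES), size=length))


def is_strict_dna(seq: str) -> bool:
    return all(c in _BASE_SET for c in seq)


def hamming(a: str, b: str) -> int:
    """Number of differing positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def substitute(seq: str, positions, rng: np.random.Generator) -> str:
    """Replace each listed position with a uniformly drawn *different* base."""
    out = list(seq)
    for pos in positions:
        old = out[pos]
        choices = [b for b in BASES if b != old]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def homopolymer_runs(seq: str, min_run: int = 6) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of single-base runs of length >= min_run."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs
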