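"""Low-level sequence helpers shared by the scanners.

Sequences are plain uppercase Python strings over {A,C,G,T,N}; the scanners
convert them once to uint8 numpy arrays for vectorised window comparisons.
Ambiguity characters (anything outside ACGT) never match anything, including
themselves — conservative and deterministic.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Byte-level complement table. Non-ACGT bytes map to 0, a value that never
# occurs in a sequence byte, so an ambiguous base can never complement-match.
_COMP_BYTES = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_BYTES[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements for string round-trips)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_bytes(seq: str) -> np.ndarray:
    """Sequence as a read-only uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def complement_bytes(arr: np.ndarray) -> np.ndarray:
    """Per-base complement in byte space; ambiguous bases become 0 so they
    mismatch everything."""
    return _COMP_BYTES[arr]


def hamming(a: str, b: str) -> int:
    """Hamming distance; non-ACGT characters mismatch even when identical."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    acgt = set("ACGT")
    return sum(1 for x, y in zip(a, b) if x != y or x not in acgt)


def window_mismatches(arr: np.ndarray, pattern: bytes) -> np.ndarray:
    """Hamming distance of ``pattern`` against every window of ``arr``.

    Returns an int array of length ``len(arr) - len(pattern) + 1``; windows
    containing non-ACGT bases accrue a mismatch at those positions because
    pattern bytes are always ACGT.
    """
    k = len(pattern)
    n = arr.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j, pb in enumerate(pattern):
        mm += arr[j : j + n] != pb
    return mm
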