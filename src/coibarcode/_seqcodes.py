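"""Integer encoding of aligned DNA for vectorised pairwise computation.

A, C, G, T map to 0..3 so that purines (A=0, G=2) are even and
pyrimidines (C=1, T=3) are odd: a mismatch between codes of equal parity
is a transition, unequal parity a transversion.  Gaps and ambiguity codes
map to MISSING and are excluded pair-by-pair (pairwise deletion).
"""

from __future__ import annotations

import numpy as np

MISSING = 4

_LUT = np.full(256, MISSING, dtype=np.uint8)
for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
    _LUT[ord(base)] = code


def encode_sequence(seq: str) -> np.ndarray:
    """Encode one sequence into uint8 codes (MISSING for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def encode_alignment(sequences) -> np.ndarray:
    """Encode an iterable of equal-length sequences into an (n, L) array."""
    return np.vstack([encode_sequence(s) for s in sequences])


def pair_site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(identical, transitions, transversions) over comparable sites."""
    ok = (a != MISSING) & (b != MISSING)
    diff = ok & (a != b)
    transitions = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    transversions = int(np.count_nonzero(diff) - transitions)
    identical = int(np.count_nonzero(ok) - transitions - transversions)
    return identical, transitions, transversions
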