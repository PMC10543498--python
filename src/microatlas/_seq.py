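"""Low-level nucleotide encoding helpers shared across modules.

Sequences are handled as numpy uint8 arrays with the 2-bit encoding
A=0, C=1, G=2, T=3; any other character encodes as 255 ("invalid").
K-mers are packed into uint64 codes (base-4 positional), which bounds
usable k at 31.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTacgt", "TGCAtgca")


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes (255 for non-ACGT)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def array_to_seq(arr: np.ndarray) -> str:
    """Decode a 2-bit code array back into an uppercase string."""
    if arr.size and arr.max() > 3:
        raise ValueError("array contains invalid base codes")
    return _DEC[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMP_STR)[::-1]


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    out = np.where(arr < 4, 3 - arr, arr)
    return out[::-1]


def _window_valid(arr: np.ndarray, k: int) -> np.ndarray:
    """True for windows containing only ACGT (via cumulative invalid counts)."""
    inv = (arr >= 4).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(inv)))
    return (csum[k:] - csum[: arr.size - k + 1]) == 0


def _rolling_codes(safe: np.ndarray, k: int) -> np.ndarray:
    """Packed base-4 code of every window of a 2-bit array (Horner scheme)."""
    n = safe.size - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    s64 = safe.astype(np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        codes |= s64[j : j + n]
    return codes


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes over all windows of ``arr``.

    Returns ``(codes, valid)`` of length ``len(arr) - k + 1``: ``codes[i]``
    is min(forward, reverse-complement) packed code of window ``i`` and
    ``valid[i]`` is False where the window contains a non-ACGT base.
    Callers must mask by ``valid`` before trusting ``codes``.
    """
    n = arr.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, dtype=bool)
    valid = _window_valid(arr, k)
    safe = np.where(arr < 4, arr, 0).astype(np.uint8)
    fwd = _rolling_codes(safe, k)
    rc_safe = (3 - safe)[::-1]
    rev = _rolling_codes(rc_safe, k)[::-1]
    return np.minimum(fwd, rev), valid


def forward_kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-specific (non-canonical) packed k-mer codes plus validity mask."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    valid = _window_valid(arr, k)
    safe = np.where(arr < 4, arr, 0).astype(np.uint8)
    return _rolling_codes(safe, k), valid
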