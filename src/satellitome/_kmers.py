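"""Vectorised canonical k-mer encoding.

k-mers are packed 2 bits/base into int64 (k <= 31); the canonical form is
the minimum of a k-mer and its reverse complement, making every comparison
strand-symmetric. Windows containing non-ACGT symbols are dropped.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Per-base 2-bit codes; -1 for non-ACGT."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of *seq*."""
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    win = win[valid].astype(np.int64)
    if win.size == 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win[:, ::-1]) @ powers
    return np.unique(np.minimum(fwd, rc))


def shares_kmer(read_kmers: np.ndarray, sorted_catalog: np.ndarray) -> bool:
    """True when any read k-mer occurs in the sorted catalog k-mer array."""
    if read_kmers.size == 0 or sorted_catalog.size == 0:
        return False
    idx = np.searchsorted(sorted_catalog, read_kmers)
    idx = np.clip(idx, 0, sorted_catalog.size - 1)
    return bool(np.any(sorted_catalog[idx] == read_kmers))
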