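"""Fast 2-bit k-mer encoding shared by the quantifier and allele caller."""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lower case

_EMPTY = np.empty(0, dtype=np.uint64)


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``seq``; k-mers containing non-ACGT bases are dropped.

    The code of a k-mer is its base-4 big-endian value (A=0..T=3); with
    k <= 31 this fits exactly in uint64.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in 1..31")
    n = len(seq)
    if n < k:
        return _EMPTY
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes != 255
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    vals = (windows.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    if valid.all():
        return vals
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return vals[ok]


def kmer_set(seq: str, k: int) -> set[int]:
    return set(encode_kmers(seq, k).tolist())


def spanning_kmer_set(seq: str, start: int, end: int, k: int) -> set[int]:
    """k-mers of ``seq`` whose window overlaps positions [start, end)."""
    lo = max(0, start - k + 1)
    hi = min(len(seq), end + k - 1)
    window = seq[lo:hi]
    out: set[int] = set()
    for i, code in enumerate(encode_kmers(window, k).tolist()):
        w0 = lo + i
        if w0 < end and start < w0 + k:
            out.add(code)
    return out
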