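"""Vectorised k-mer encoding shared by the synteny and region-search code."""

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
for i, b in enumerate(b"acgt"):
    _LUT[b] = i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 array of 0..3 (255 for non-ACGT)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of every k-mer of ``seq`` (base-4 packed, int64).

    Returns an empty array when the sequence is shorter than k. Any window
    containing a non-ACGT character gets code -1.
    """
    arr = encode(seq)
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        window = arr[j : j + m]
        codes = codes * 4 + np.where(window == 255, 0, window).astype(np.int64)
        bad |= window == 255
    codes[bad] = -1
    return codes


def match_positions(
    codes_a: np.ndarray,
    codes_b_sorted: np.ndarray,
    order_b: np.ndarray,
    max_multiplicity: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with codes_a[i] == codes_b[j], skipping repetitive codes.

    ``codes_b_sorted`` / ``order_b`` are ``np.sort`` / ``np.argsort`` of the
    b-side codes. k-mers occurring more than ``max_multiplicity`` times on
    the b side are ignored (repeat suppression).
    """
    if codes_a.size == 0 or codes_b_sorted.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    left = np.searchsorted(codes_b_sorted, codes_a, side="left")
    right = np.searchsorted(codes_b_sorted, codes_a, side="right")
    cnt = right - left
    keep = (cnt > 0) & (cnt <= max_multiplicity) & (codes_a >= 0)
    idx_a = np.nonzero(keep)[0]
    if idx_a.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    cnt_k = cnt[keep]
    starts = left[keep]
    a_rep = np.repeat(idx_a, cnt_k)
    # ranges [starts, starts+cnt) flattened
    offs = np.arange(cnt_k.sum()) - np.repeat(np.cumsum(cnt_k) - cnt_k, cnt_k)
    b_rep = order_b[np.repeat(starts, cnt_k) + offs]
    return a_rep, b_rep
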