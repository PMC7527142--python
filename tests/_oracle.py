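"""Brute-force synteny-block oracle, independent of the package's chainer.

Enumerates every exact k-mer match with plain dictionaries, merges
collinear matches transitively under the break rule (nonhomologous stretch
<= max_gap on both sequences), and picks the block subset maximizing total
coverage by exhaustive subset search. Only suitable for short sequences.
"""

import itertools

from syntrack.genome import revcomp


def _anchors(a: str, b: str, k: int) -> list[tuple[int, int]]:
    pos: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        pos.setdefault(b[j : j + k], []).append(j)
    out = []
    for i in range(len(a) - k + 1):
        for j in pos.get(a[i : i + k], ()):
            out.append((i, j))
    return out


def _chain(anchors: list[tuple[int, int]], k: int, max_gap: int) -> list[list[int]]:
    """Transitive merge of collinear anchors into [a_s, a_e, b_s, b_e] runs."""
    anchors = sorted(anchors)
    chains: list[list[int]] = []
    for i, j in anchors:
        placed = False
        for c in chains:
            gap_a = i - (c[1] + 1)
            gap_b = j - (c[3] + 1)
            if -k <= gap_a <= max_gap and -k <= gap_b <= max_gap and j > c[3] - k:
                c[1] = max(c[1], i + k - 1)
                c[3] = max(c[3], j + k - 1)
                placed = True
                break
        if not placed:
            chains.append([i, i + k - 1, j, j + k - 1])
    return chains


def oracle_blocks(
    a: str, b: str, k: int = 13, max_gap: int = 15, min_len: int | None = None
) -> tuple[int, int]:
    """(n_blocks, sum of block spans on the shorter sequence's side)."""
    if min_len is None:
        min_len = 2 * k
    if a == b and len(a) >= k:
        return 1, min(len(a), len(b))
    cands = []
    for strand, bb in (("+", b), ("-", revcomp(b))):
        for c in _chain(_anchors(a, bb, k), k, max_gap):
            a_s, a_e, b_s, b_e = c
            if strand == "-":
                b_s, b_e = len(b) - 1 - c[3], len(b) - 1 - c[2]
            if min(a_e - a_s, b_e - b_s) + 1 >= min_len:
                cands.append((a_s, a_e, b_s, b_e, strand))
    short_a = len(a) <= len(b)
    best = (0, 0)
    for r in range(len(cands) + 1):
        for subset in itertools.combinations(cands, r):
            ok = True
            for x, y in itertools.combinations(subset, 2):
                if min(x[1], y[1]) - max(x[0], y[0]) + 1 > k:
                    ok = False
                    break
                if min(x[3], y[3]) - max(x[2], y[2]) + 1 > k:
                    ok = False
                    break
            if not ok:
                continue
            cov = sum(
                (c[1] - c[0] + 1) if short_a else (c[3] - c[2] + 1) for c in subset
            )
            if cov > best[1] or (cov == best[1] and r < best[0]):
                best = (r, cov)
    n, cov = best
    return n, min(cov, min(len(a), len(b)))
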