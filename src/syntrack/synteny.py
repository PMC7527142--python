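"""Pairwise synteny-block decomposition and the synteny score.

Two homologous regions are decomposed into synteny blocks: maximal
collinear stretches of shared sequence, on either strand, separated by
breaks. A break is a nonhomologous stretch longer than ``max_gap`` (15 bp
by default) on either sequence, or a strand change. The synteny score of a
comparison with ``n`` blocks of summed length ``sum_Lsb`` over a shorter
sequence of length ``Lseq`` is::

    Syn_score = 1 + log10(sum_Lsb / (Lseq * n))

so a single block covering the whole shorter sequence scores exactly 1 and
every extra break or loss of coverage pushes the score down.

Block finding is seed-and-chain: exact k-mer anchors (default k = 13) on
both strands are grouped into same-diagonal runs, runs are merged across
nearby diagonals when the intervening nonhomologous stretch is at most
``max_gap`` on BOTH sequences, and conflicting claims are resolved by
weighted interval scheduling on anchored coverage.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from syntrack._kmers import kmer_codes, match_positions
from syntrack.genome import revcomp

logger = logging.getLogger(__name__)


@dataclass
class SyntenyParams:
    k: int = 13
    max_gap: int = 15
    min_block_len: int | None = None  # defaults to 2 * k
    count_inverted_blocks: bool = True
    max_multiplicity: int = 8

    @property
    def min_len(self) -> int:
        return 2 * self.k if self.min_block_len is None else self.min_block_len


@dataclass(frozen=True)
class SyntenyBlock:
    """One synteny block; coordinates 1-based inclusive on each sequence."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    length: int  # span on the shorter-sequence side

    def __post_init__(self):
        if self.a_end < self.a_start or self.b_end < self.b_start or self.length < 1:
            raise ValueError("degenerate synteny block")


@dataclass
class SyntenyComparison:
    region_id: str
    sample_a: str
    sample_b: str
    blocks: list[SyntenyBlock]
    lseq: int
    n: int = field(init=False)
    sum_lsb: int = field(init=False)
    score: float | None = field(init=False)

    def __post_init__(self):
        self.n = len(self.blocks)
        self.sum_lsb = min(sum(b.length for b in self.blocks), self.lseq)
        self.score = synteny_score(self)


def synteny_score(comparison: "SyntenyComparison") -> float | None:
    """Score a comparison; ``None`` (undefined) when no block was found."""
    return score_from_counts(comparison.n, comparison.sum_lsb, comparison.lseq)


def score_from_counts(n: int, sum_lsb: float, lseq: float) -> float | None:
    if lseq < 1:
        raise ValueError("Lseq must be >= 1")
    if n == 0:
        return None
    sum_lsb = min(sum_lsb, lseq)
    return 1.0 + math.log10(sum_lsb / (lseq * n))


# ---------------------------------------------------------------------------
# Anchor chaining


class SequenceProfile:
    """Cached k-mer codes of one sequence, for repeated comparisons."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        self.length = len(seq)
        self.codes = kmer_codes(seq, k)
        self.fwd_order = np.argsort(self.codes, kind="stable")
        self.fwd_sorted = self.codes[self.fwd_order]
        rc_codes = kmer_codes(revcomp(seq), k)
        self.rc_order = np.argsort(rc_codes, kind="stable")
        self.rc_sorted = rc_codes[self.rc_order]


def _diagonal_runs(ia: np.ndarray, jb: np.ndarray, k: int, max_gap: int) -> list[list[int]]:
    """Group anchors into same-diagonal runs; returns [a_s, a_e, b_s, b_e, w].

    Coordinates are 0-based inclusive; ``w`` is the anchored coverage of the
    run (number of a-positions covered by its anchors).
    """
    if ia.size == 0:
        return []
    d = jb - ia
    order = np.lexsort((ia, d))
    ia_s, jb_s, d_s = ia[order], jb[order], d[order]
    new = np.empty(ia_s.size, dtype=bool)
    new[0] = True
    diffs = ia_s[1:] - ia_s[:-1]
    new[1:] = (d_s[1:] != d_s[:-1]) | (diffs > max_gap + k)
    covered = np.minimum(diffs, k)
    covered[new[1:]] = 0
    cov_cum = np.concatenate([[0], np.cumsum(covered)])
    starts = np.nonzero(new)[0]
    ends = np.append(starts[1:], ia_s.size) - 1
    runs = []
    for s, e in zip(starts, ends):
        w = int(cov_cum[e] - cov_cum[s]) + k
        runs.append([int(ia_s[s]), int(ia_s[e]) + k - 1, int(jb_s[s]), int(jb_s[e]) + k - 1, w])
    return runs


def _merge_collinear(runs: list[list[int]], k: int, max_gap: int) -> list[list[int]]:
    """Merge collinear runs whose gaps are <= max_gap on both sequences."""
    runs = sorted(runs, key=lambda r: (r[0], r[2]))
    out: list[list[int]] = []
    for r in runs:
        merged = False
        for t in reversed(out):
            gap_a = r[0] - (t[1] + 1)
            gap_b = r[2] - (t[3] + 1)
            if -k <= gap_a <= max_gap and -k <= gap_b <= max_gap and r[3] > t[3]:
                t[1] = max(t[1], r[1])
                t[3] = max(t[3], r[3])
                t[4] += r[4]
                merged = True
                break
            if gap_a > max_gap:
                break
        if not merged:
            out.append(list(r))
    return out


def _select_compatible(cands: list[list], tol: int) -> list[list]:
    """Weighted interval scheduling on the a-axis (overlap up to tol allowed),
    then a greedy b-axis overlap filter by descending weight."""
    if len(cands) <= 1:
        return list(cands)
    cands = sorted(cands, key=lambda c: c[1])
    ends = [c[1] for c in cands]
    n = len(cands)
    # p[i]: rightmost j < i with ends[j] <= start_i - 1 + tol
    import bisect

    p = [bisect.bisect_right(ends, cands[i][0] - 1 + tol, 0, i) - 1 for i in range(n)]
    dp = [0.0] * (n + 1)
    take = [False] * n
    for i in range(n):
        with_i = cands[i][4] + dp[p[i] + 1]
        if with_i > dp[i]:
            dp[i + 1] = with_i
            take[i] = True
        else:
            dp[i + 1] = dp[i]
    chosen = []
    i = n - 1
    while i >= 0:
        if take[i]:
            chosen.append(cands[i])
            i = p[i]
        else:
            i -= 1
    chosen.reverse()
    # resolve residual overlaps on b
    kept: list[list] = []
    for c in sorted(chosen, key=lambda c: -c[4]):
        ok = True
        for t in kept:
            ov = min(c[3], t[3]) - max(c[2], t[2]) + 1
            if ov > tol:
                ok = False
                break
        if ok:
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return kept


def find_synteny_blocks(
    seq_a: str,
    seq_b: str,
    max_gap: int = 15,
    k: int = 13,
    params: SyntenyParams | None = None,
    profile_a: SequenceProfile | None = None,
    profile_b: SequenceProfile | None = None,
) -> list[SyntenyBlock]:
    """Decompose a pair of sequences into synteny blocks.

    Zero blocks is a valid result (no homology detectable). Blocks are
    reported in seq_a order with 1-based inclusive coordinates.
    """
    if params is None:
        params = SyntenyParams(k=k, max_gap=max_gap)
    k = params.k
    max_gap = params.max_gap
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    len_a, len_b = len(seq_a), len(seq_b)
    short_is_a = len_a <= len_b
    if seq_a == seq_b and len_a >= k:
        return [SyntenyBlock(1, len_a, 1, len_b, "+", len_a)]
    if min(len_a, len_b) < k:
        return []

    pa = profile_a if profile_a is not None else SequenceProfile(seq_a, k)
    pb = profile_b if profile_b is not None else SequenceProfile(seq_b, k)

    cands: list[list] = []
    # forward strand
    ia, jb = match_positions(pa.codes, pb.fwd_sorted, pb.fwd_order, params.max_multiplicity)
    for c in _merge_collinear(_diagonal_runs(ia, jb, k, max_gap), k, max_gap):
        cands.append(c + ["+"])
    # reverse strand: chain in revcomp(b) space, then map back
    ia, jb = match_positions(pa.codes, pb.rc_sorted, pb.rc_order, params.max_multiplicity)
    for c in _merge_collinear(_diagonal_runs(ia, jb, k, max_gap), k, max_gap):
        b_s = len_b - 1 - c[3]
        b_e = len_b - 1 - c[2]
        cands.append([c[0], c[1], b_s, b_e, c[4], "-"])

    if not params.count_inverted_blocks:
        cands = [c for c in cands if c[5] == "+"]
    # drop sub-minimal candidates early (chance seeds)
    cands = [
        c
        for c in cands
        if min(c[1] - c[0], c[3] - c[2]) + 1 >= params.min_len
    ]
    kept = _select_compatible(cands, tol=k)
    blocks = []
    for a_s, a_e, b_s, b_e, _w, strand in kept:
        span = (a_e - a_s + 1) if short_is_a else (b_e - b_s + 1)
        blocks.append(SyntenyBlock(a_s + 1, a_e + 1, b_s + 1, b_e + 1, strand, span))
    return blocks


def compare_sequences(
    region_id: str,
    sample_a: str,
    sample_b: str,
    seq_a: str,
    seq_b: str,
    params: SyntenyParams | None = None,
    profile_a: SequenceProfile | None = None,
    profile_b: SequenceProfile | None = None,
) -> SyntenyComparison:
    params = params or SyntenyParams()
    blocks = find_synteny_blocks(
        seq_a, seq_b, params=params, profile_a=profile_a, profile_b=profile_b
    )
    return SyntenyComparison(region_id, sample_a, sample_b, blocks, min(len(seq_a), len(seq_b)))


def _region_items(region_set) -> dict[str, dict[str, str]]:
    """Accept a RegionSet or a plain {region: {sample: sequence}} mapping."""
    regions = getattr(region_set, "regions", region_set)
    out = {}
    for rid, by_sample in regions.items():
        out[rid] = {
            s: (hit.sequence if hasattr(hit, "sequence") else hit)
            for s, hit in by_sample.items()
        }
    return out


def compare_all(region_set, params: SyntenyParams | None = None) -> list[SyntenyComparison]:
    """All unordered pairwise comparisons, per region, in deterministic order."""
    params = params or SyntenyParams()
    regions = _region_items(region_set)
    results = []
    n_undefined = 0
    for rid in sorted(regions):
        by_sample = regions[rid]
        samples = sorted(by_sample)
        # identical extracted sequences (same strain, same clipping) are
        # common in a cohort; compare each unique sequence pair once
        uniq: dict[str, int] = {}
        uid = {s: uniq.setdefault(by_sample[s], len(uniq)) for s in samples}
        seqs = list(uniq)
        profiles = [SequenceProfile(seq, params.k) for seq in seqs]
        cache: dict[tuple[int, int], list[SyntenyBlock]] = {}
        for sa, sb in itertools.combinations(samples, 2):
            ia, ib = uid[sa], uid[sb]
            blocks = cache.get((ia, ib))
            if blocks is None:
                blocks = find_synteny_blocks(
                    seqs[ia],
                    seqs[ib],
                    params=params,
                    profile_a=profiles[ia],
                    profile_b=profiles[ib],
                )
                cache[(ia, ib)] = blocks
            cmp = SyntenyComparison(
                rid, sa, sb, blocks, min(len(seqs[ia]), len(seqs[ib]))
            )
            if cmp.score is None:
                n_undefined += 1
            results.append(cmp)
    if n_undefined:
        logger.info("%d comparison(s) with zero blocks excluded as undefined", n_undefined)
    return results


def comparisons_to_frame(comparisons: list[SyntenyComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "sample_a": c.sample_a,
                "sample_b": c.sample_b,
                "n_blocks": c.n,
                "Lseq": c.lseq,
                "sum_Lsb": c.sum_lsb,
                "score": c.score,
            }
            for c in comparisons
        ],
        columns=["region_id", "sample_a", "sample_b", "n_blocks", "Lseq", "sum_Lsb", "score"],
    )


def write_scores(comparisons: list[SyntenyComparison], path: str | Path) -> None:
    df = comparisons_to_frame(comparisons)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
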