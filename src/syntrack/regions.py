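"""Query-gene selection and homologous-region retrieval from assemblies.

Randomly selected reference genes (with a minimum annotation-order gap
between them so regions cannot overlap) are searched against each sample
assembly; hits passing identity and coverage thresholds are extended by a
fixed flank on both sides, regions found in too few samples are dropped,
and the selection iterates with fresh genes until enough regions survive.

The homology search is seed-and-extend: exact k-mer seeding on both
strands followed by local alignment (match +1, mismatch -2, gap open -4,
gap extend -1) of the query against the seeded contig window. At the >= 97%
identity regime this is an adequate stand-in for a BLASTn search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from syntrack._kmers import kmer_codes
from syntrack.genome import AnnotatedGenome, revcomp

logger = logging.getLogger(__name__)


@dataclass
class RegionSearchParams:
    min_identity: float = 0.97
    min_coverage: float = 0.90
    flank: int = 3500
    min_prevalence: int = 16  # strictly more than 15 samples
    min_regions: int = 4
    min_gene_gap: int = 5
    max_iterations: int = 10
    seed_k: int = 15

    def __post_init__(self):
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class RegionHit:
    """Best homology hit of one query gene in one sample assembly."""

    sample_id: str
    contig_id: str
    start: int  # 1-based inclusive, contig plus-strand coordinates
    end: int
    strand: str
    identity: float
    coverage: float
    sequence: str | None = None  # hit +- flank, query orientation
    clipped_left: int = 0  # flank bp unavailable at the returned sequence start
    clipped_right: int = 0


@dataclass
class RegionSet:
    """Regions (query genes) mapped to their per-sample hits."""

    regions: dict[str, dict[str, RegionHit]] = field(default_factory=dict)
    complete: bool = False
    rounds: list[dict] = field(default_factory=list)  # per-iteration provenance


# ---------------------------------------------------------------------------
# Gene selection


def _max_feasible(n_genes: int, min_gene_gap: int) -> int:
    return (n_genes - 1) // (min_gene_gap + 1) + 1 if n_genes else 0


def select_candidate_genes(
    genome: AnnotatedGenome,
    n: int,
    min_gene_gap: int = 5,
    seed: int = 0,
    exclude: set[str] | None = None,
) -> list[str]:
    """Uniformly sample ``n`` genes with >= ``min_gene_gap`` genes between picks.

    The gap is counted in annotation order. Without exclusions the sample is
    exactly uniform over all feasible index sets (via the standard
    gap-subset bijection); with exclusions (iteration rounds) a shuffled
    greedy pick is used instead. Raises ``ValueError`` naming the maximum
    feasible ``n`` when the constraint cannot be met.
    """
    G = len(genome.genes)
    step = min_gene_gap + 1
    rng = np.random.default_rng(seed)
    if exclude:
        order = rng.permutation(G)
        chosen: list[int] = []
        excluded_idx = {i for i, g in enumerate(genome.genes) if g.gene_id in exclude}
        for i in order:
            if i in excluded_idx:
                continue
            if all(abs(i - j) >= step for j in chosen):
                chosen.append(int(i))
                if len(chosen) == n:
                    break
        if len(chosen) < n:
            raise ValueError(
                f"cannot select {n} genes with gap {min_gene_gap}; "
                f"only {len(chosen)} feasible given exclusions"
            )
        return [genome.genes[i].gene_id for i in sorted(chosen)]
    max_n = _max_feasible(G, min_gene_gap)
    if n > max_n:
        raise ValueError(
            f"cannot select {n} genes with gap {min_gene_gap} from {G}; "
            f"maximum feasible n is {max_n}"
        )
    m = G - (n - 1) * (step - 1)
    ys = np.sort(rng.choice(m, size=n, replace=False))
    idx = [int(y) + i * (step - 1) for i, y in enumerate(ys)]
    return [genome.genes[i].gene_id for i in idx]


# ---------------------------------------------------------------------------
# Homology search


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _contig_seq(contig) -> tuple[str, str]:
    """Accept Contig objects, (id, seq) tuples, or dict items."""
    if hasattr(contig, "contig_id"):
        return contig.contig_id, contig.sequence
    cid, seq = contig
    return cid, seq


class AssemblyIndex:
    """Pre-computed k-mer index of an assembly, reusable across queries."""

    def __init__(self, contigs, k: int):
        self.k = k
        self.contigs = [_contig_seq(c) for c in contigs]
        self.entries = []  # (cid, cseq, strand, oriented_seq, sorted_codes, order)
        for cid, cseq in self.contigs:
            if len(cseq) < k:
                continue
            for strand in "+-":
                oriented = cseq if strand == "+" else revcomp(cseq)
                codes = kmer_codes(oriented, k)
                order = np.argsort(codes, kind="stable")
                self.entries.append((cid, cseq, strand, oriented, codes[order], order))

    def __iter__(self):
        return iter(self.contigs)


def _candidate_windows(
    query_codes: np.ndarray, contig_codes_sorted, contig_order, qlen: int, clen: int
) -> list[tuple[int, int]]:
    """Diagonal-clustered seed hits -> candidate contig windows (0-based)."""
    from syntrack._kmers import match_positions

    qi, cj = match_positions(query_codes, contig_codes_sorted, contig_order, 16)
    if qi.size == 0:
        return []
    d = cj - qi
    order = np.argsort(d)
    d = d[order]
    band = max(50, qlen // 5)
    split = np.nonzero(np.diff(d) > band)[0]
    bounds = np.concatenate([[0], split + 1, [d.size]])
    margin = 50 + qlen // 10
    windows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        lo = int(d[s]) - margin
        hi = int(d[e - 1]) + qlen + margin
        windows.append((max(0, lo), min(clen, hi)))
    # merge overlapping windows
    windows.sort()
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _align_window(query: str, window: str) -> tuple[float, float, int, int, int] | None:
    """Local-align query to window; returns (identity, coverage, aligned_len,
    t_start, t_end) with t coordinates 0-based half-open in the window."""
    alns = _ALIGNER.align(window, query)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_len += te - ts
        tseg = window[ts:te]
        qseg = query[qs:qe]
        matches += sum(1 for x, y in zip(tseg, qseg) if x == y)
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    t_span = t_end - t_start
    q_span = q_end - q_start
    columns = t_span + q_span - aligned_len
    identity = matches / columns if columns else 0.0
    coverage = aligned_len / len(query)
    return identity, coverage, aligned_len, t_start, t_end


def search_gene(
    gene_sequence: str,
    assembly,
    params: RegionSearchParams | None = None,
    sample_id: str = "",
) -> RegionHit | None:
    """Best above-threshold hit of a query gene in an assembly, or ``None``.

    The best hit maximizes identity x coverage; ties broken by longer
    alignment, then lexicographic contig id, then leftmost start. Queries
    shorter than ~100 bp are unreliable with the default seed length.
    """
    params = params or RegionSearchParams()
    qlen = len(gene_sequence)
    k = params.seed_k
    if qlen < k:
        return None
    index = assembly if isinstance(assembly, AssemblyIndex) else AssemblyIndex(assembly, k)
    qcodes = kmer_codes(gene_sequence, k)
    best = None
    best_key = None
    for cid, cseq, strand, oriented, csorted, order in index.entries:
        for lo, hi in _candidate_windows(qcodes, csorted, order, qlen, len(oriented)):
            res = _align_window(gene_sequence, oriented[lo:hi])
            if res is None:
                continue
            identity, coverage, alen, t_s, t_e = res
            if identity < params.min_identity or coverage < params.min_coverage:
                continue
            # map to contig plus-strand 1-based coordinates
            o_s, o_e = lo + t_s, lo + t_e  # 0-based half-open, oriented
            if strand == "+":
                start, end = o_s + 1, o_e
            else:
                start, end = len(cseq) - o_e + 1, len(cseq) - o_s
            key = (identity * coverage, alen, _NegStr(cid), -start)
            if best_key is None or key > best_key:
                if best is not None and best.contig_id != cid:
                    logger.debug("multiple above-threshold hits; keeping best")
                best_key = key
                best = RegionHit(sample_id, cid, start, end, strand, identity, coverage)
    return best


class _NegStr(str):
    """Reverses string comparison so max() prefers lexicographically smaller ids."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def extract_flanked_region(hit: RegionHit, assembly, flank: int = 3500) -> RegionHit:
    """Extend a hit by ``flank`` bp on both sides, clipped at contig ends.

    Returns a copy of the hit with ``sequence`` set (reverse-complemented to
    query orientation for minus-strand hits) and clipped flank lengths
    recorded relative to the returned sequence's orientation.
    """
    cseq = None
    for contig in assembly:
        cid, seq = _contig_seq(contig)
        if cid == hit.contig_id:
            cseq = seq
            break
    if cseq is None:
        raise ValueError(f"contig {hit.contig_id} not in assembly")
    lo = max(1, hit.start - flank)
    hi = min(len(cseq), hit.end + flank)
    clip_low = flank - (hit.start - lo)
    clip_high = flank - (hi - hit.end)
    seq = cseq[lo - 1 : hi]
    if hit.strand == "-":
        seq = revcomp(seq)
        clip_left, clip_right = clip_high, clip_low
    else:
        clip_left, clip_right = clip_low, clip_high
    return replace(hit, sequence=seq, clipped_left=clip_left, clipped_right=clip_right)


# ---------------------------------------------------------------------------
# Region-set construction


def build_region_set(
    genome: AnnotatedGenome,
    assemblies: dict[str, list],
    params: RegionSearchParams | None = None,
    seed: int = 0,
    n_genes_per_round: int = 5,
) -> RegionSet:
    """Iterate select -> search -> extract until enough regions survive.

    Regions found in fewer than ``min_prevalence`` samples are dropped.
    Iteration draws fresh genes (never reusing tried ones, still honoring
    the gene gap against kept genes) until ``min_regions`` survive, the
    gene pool is exhausted, or ``max_iterations`` rounds have run. An
    under-filled set is returned with ``complete=False``.
    """
    params = params or RegionSearchParams()
    if not assemblies:
        raise ValueError("at least one assembly is required")
    result = RegionSet()
    tried: set[str] = set()
    kept_genes: set[str] = set()
    indexes = {
        sid: asm if isinstance(asm, AssemblyIndex) else AssemblyIndex(asm, params.seed_k)
        for sid, asm in assemblies.items()
    }
    for round_no in range(params.max_iterations):
        want = max(n_genes_per_round, params.min_regions - len(result.regions))
        try:
            candidates = select_candidate_genes(
                genome,
                want,
                params.min_gene_gap,
                seed=seed + round_no if round_no else seed,
                exclude=tried | kept_genes,
            )
        except ValueError:
            # try progressively smaller batches before giving up
            candidates = []
            for smaller in range(want - 1, 0, -1):
                try:
                    candidates = select_candidate_genes(
                        genome,
                        smaller,
                        params.min_gene_gap,
                        seed=seed + round_no if round_no else seed,
                        exclude=tried | kept_genes,
                    )
                    break
                except ValueError:
                    continue
            if not candidates:
                break
        round_info = {"round": round_no, "genes_tried": list(candidates), "kept": []}
        for gid in candidates:
            tried.add(gid)
            qseq = genome.gene_sequence(gid)
            hits = {}
            for sample_id in sorted(assemblies):
                hit = search_gene(qseq, indexes[sample_id], params, sample_id=sample_id)
                if hit is not None:
                    hits[sample_id] = extract_flanked_region(
                        hit, indexes[sample_id], params.flank
                    )
            if len(hits) >= params.min_prevalence:
                result.regions[gid] = hits
                kept_genes.add(gid)
                round_info["kept"].append(gid)
            else:
                logger.info(
                    "region %s found in %d sample(s) (< %d); dropped",
                    gid,
                    len(hits),
                    params.min_prevalence,
                )
        result.rounds.append(round_info)
        if len(result.regions) >= params.min_regions:
            break
    result.complete = len(result.regions) >= params.min_regions
    return result


def region_summary(region_set: RegionSet) -> pd.DataFrame:
    rows = []
    for rid in sorted(region_set.regions):
        for sid in sorted(region_set.regions[rid]):
            h = region_set.regions[rid][sid]
            rows.append(
                {
                    "region_id": rid,
                    "sample_id": sid,
                    "contig": h.contig_id,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "identity": round(h.identity, 6),
                    "coverage": round(h.coverage, 6),
                    "clipped_left": h.clipped_left,
                    "clipped_right": h.clipped_right,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "sample_id",
            "contig",
            "start",
            "end",
            "strand",
            "identity",
            "coverage",
            "clipped_left",
            "clipped_right",
        ],
    )


def write_region_set(region_set: RegionSet, outdir: str | Path) -> None:
    """Write regions/<region_id>/<sample_id>.fasta plus region_summary.tsv."""
    from syntrack.genome import write_fasta

    out = Path(outdir)
    reg_dir = out / "regions"
    for rid, hits in region_set.regions.items():
        d = reg_dir / rid
        d.mkdir(parents=True, exist_ok=True)
        for sid, h in hits.items():
            write_fasta(d / f"{sid}.fasta", {f"{rid}|{sid}": h.sequence})
    region_summary(region_set).to_csv(out / "region_summary.tsv", sep="\t", index=False)
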