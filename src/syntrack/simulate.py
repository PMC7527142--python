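"""Synthetic twin-cohort genome simulator.

Generates an ancestral bacterial genome, derives strains from it by SNPs,
short indels, inversions and translocations (with a replayable event log),
assigns strains to a twin-structured longitudinal cohort, degrades each
sample's genome into an incomplete assembly, and emits a per-sample variant
table plus ground-truth metadata.

The default :class:`CohortDesign` mirrors a 46-sample longitudinal twin
study: 11 individuals per host genotype (GG lactase-nonpersistent vs AA
persistent), 4 monozygotic twin pairs per genotype, 20 individuals with 2
timepoints and 2 with 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from syntrack._seeds import derive_seed, rng_for
from syntrack.genome import AnnotatedGenome, Gene, revcomp, write_fasta, write_genome

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class Event:
    """One mutation event, with coordinates valid at its application time.

    ``position`` is 1-based. For ``insertion`` the payload is inserted after
    ``position`` (0 = before the first base). For segment events ``end`` is
    the inclusive segment end; for ``translocation`` ``dest`` is the 1-based
    insertion point in post-excision coordinates (segment re-inserted so it
    starts at ``dest``).
    """

    type: str  # snp | insertion | deletion | inversion | translocation
    position: int
    length: int = 1
    end: int = 0
    dest: int = 0
    payload: str = ""


@dataclass
class StrainEventLog:
    strain_id: str
    parent_id: str
    events: list[Event] = field(default_factory=list)


def _liftover_deletion(genes: list[Gene], del_s: int, del_e: int) -> list[Gene]:
    L = del_e - del_s + 1
    out = []
    for g in genes:
        if g.end < del_s:
            out.append(g)
        elif g.start > del_e:
            out.append(replace(g, start=g.start - L, end=g.end - L))
        else:
            new_s = g.start if g.start < del_s else del_s
            new_e = g.end - L if g.end > del_e else del_s - 1
            if new_e >= new_s:
                out.append(replace(g, start=new_s, end=new_e))
            # gene fully deleted -> dropped
    return out


def _liftover_insertion(genes: list[Gene], pos: int, L: int) -> list[Gene]:
    out = []
    for g in genes:
        if g.start > pos:
            out.append(replace(g, start=g.start + L, end=g.end + L))
        elif g.end > pos:
            out.append(replace(g, end=g.end + L))
        else:
            out.append(g)
    return out


def apply_event(seq: str, genes: list[Gene], ev: Event) -> tuple[str, list[Gene]]:
    """Apply one event to a sequence and lift gene coordinates over."""
    if ev.type == "snp":
        p = ev.position
        return seq[: p - 1] + ev.payload + seq[p:], list(genes)
    if ev.type == "insertion":
        p = ev.position
        return seq[:p] + ev.payload + seq[p:], _liftover_insertion(genes, p, len(ev.payload))
    if ev.type == "deletion":
        s, L = ev.position, ev.length
        e = s + L - 1
        return seq[: s - 1] + seq[e:], _liftover_deletion(genes, s, e)
    if ev.type == "inversion":
        s, e = ev.position, ev.end
        new_seq = seq[: s - 1] + revcomp(seq[s - 1 : e]) + seq[e:]
        out = []
        for g in genes:
            if g.end < s or g.start > e:
                out.append(g)
            elif g.start >= s and g.end <= e:
                flipped = "-" if g.strand == "+" else "+"
                out.append(
                    Gene(g.gene_id, s + (e - g.end), s + (e - g.start), flipped)
                )
            else:
                logger.warning("gene %s truncated by inversion; dropped", g.gene_id)
        out.sort(key=lambda g: g.start)
        return new_seq, out
    if ev.type == "translocation":
        s, e, dest = ev.position, ev.end, ev.dest
        segment = seq[s - 1 : e]
        seg_len = len(segment)
        remaining = seq[: s - 1] + seq[e:]
        new_seq = remaining[: dest - 1] + segment + remaining[dest - 1 :]
        # genes inside the segment travel with it; the rest follow
        # deletion-then-insertion arithmetic
        inside = [g for g in genes if g.start >= s and g.end <= e]
        outside = [g for g in genes if g.end < s or g.start > e]
        dropped = len(genes) - len(inside) - len(outside)
        if dropped:
            logger.warning("%d gene(s) truncated by translocation; dropped", dropped)
        lifted = _liftover_deletion(outside, s, e)
        lifted = _liftover_insertion(lifted, dest - 1, seg_len)
        moved = [
            replace(g, start=dest + (g.start - s), end=dest + (g.end - s)) for g in inside
        ]
        out = sorted(lifted + moved, key=lambda g: g.start)
        return new_seq, out
    raise ValueError(f"unknown event type {ev.type!r}")


def replay(parent: AnnotatedGenome, log: StrainEventLog) -> str:
    """Re-apply an event log to the parent; returns the strain sequence."""
    seq, genes = parent.sequence, list(parent.genes)
    for ev in log.events:
        seq, genes = apply_event(seq, genes, ev)
    return seq


# ---------------------------------------------------------------------------
# Reference and strain generation


def generate_reference(
    length_bp: int,
    n_genes: int,
    gene_length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
) -> AnnotatedGenome:
    """Uniform-random genome with ``n_genes`` non-overlapping genes.

    Genes are placed by drawing lengths uniformly from
    ``gene_length_range`` and spreading the leftover intergenic space
    uniformly between them. Raises ``ValueError`` when the genes cannot be
    packed into ``length_bp``.
    """
    lo, hi = gene_length_range
    if n_genes * lo > length_bp:
        raise ValueError(
            f"infeasible packing: {n_genes} genes of at least {lo} bp "
            f"exceed genome length {length_bp}"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_BASES, size=length_bp))
    for _ in range(100):
        lengths = rng.integers(lo, hi + 1, size=n_genes)
        if int(lengths.sum()) <= length_bp:
            break
    else:
        raise ValueError(
            f"infeasible packing: could not fit {n_genes} genes of "
            f"{lo}-{hi} bp into {length_bp} bp"
        )
    slack = length_bp - int(lengths.sum())
    # distribute slack over n_genes + 1 gaps (uniform composition)
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += int(gaps[i])
        start = pos + 1
        end = pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene_{i + 1:03d}", start, end, strand))
        pos = end
    return AnnotatedGenome(f"ref_seed{seed}", seq, genes)


def _truncates_gene(genes: list[Gene], s: int, e: int) -> bool:
    """True if [s, e] partially overlaps any gene (full containment is fine)."""
    for g in genes:
        if g.end < s or g.start > e:
            continue
        if not (g.start >= s and g.end <= e):
            return True
    return False


def _inside_gene(genes: list[Gene], pos: int) -> bool:
    return any(g.start < pos <= g.end for g in genes)


def derive_strain(
    parent: AnnotatedGenome,
    snp_rate: float = 0.005,
    indel_rate: float = 5e-4,
    n_inversions: int = 2,
    n_translocations: int = 1,
    seed: int = 0,
    strain_id: str | None = None,
    indel_mean: float = 3.0,
    segment_range: tuple[int, int] = (500, 3000),
    max_placement_attempts: int = 100,
) -> tuple[AnnotatedGenome, StrainEventLog]:
    """Derive a strain genome from ``parent`` with a replayable event log.

    SNPs are applied first (their positions are therefore parent
    coordinates, which the cohort variant table relies on), then indels of
    geometric length, then inversions and translocations whose segments
    avoid truncating genes when a non-truncating placement is found within
    ``max_placement_attempts`` draws.
    """
    rng = np.random.default_rng(seed)
    sid = strain_id if strain_id is not None else f"{parent.id}_strain{seed}"
    log = StrainEventLog(sid, parent.id)
    seq, genes = parent.sequence, list(parent.genes)
    L0 = len(seq)

    # SNPs, on parent coordinates
    n_snp = rng.binomial(L0, snp_rate)
    positions = np.sort(rng.choice(L0, size=n_snp, replace=False)) + 1
    for p in positions:
        old = seq[p - 1]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(0, 3)]
        ev = Event("snp", int(p), 1, payload=new)
        seq, genes = apply_event(seq, genes, ev)
        log.events.append(ev)

    # indels, sequentially on the current sequence
    n_indel = rng.binomial(L0, indel_rate)
    for _ in range(n_indel):
        ilen = int(rng.geometric(1.0 / indel_mean))
        if rng.random() < 0.5:
            pos = int(rng.integers(0, len(seq) + 1))
            payload = "".join(rng.choice(_BASES, size=ilen))
            ev = Event("insertion", pos, ilen, payload=payload)
        else:
            ilen = min(ilen, len(seq) - 1)
            pos = int(rng.integers(1, len(seq) - ilen + 2))
            ev = Event("deletion", pos, ilen)
        seq, genes = apply_event(seq, genes, ev)
        log.events.append(ev)

    # rearrangements
    seg_lo, seg_hi = segment_range
    for kind in ["inversion"] * n_inversions + ["translocation"] * n_translocations:
        seg_len = int(rng.integers(seg_lo, seg_hi + 1))
        seg_len = min(seg_len, len(seq) - 1)
        s = None
        for attempt in range(max_placement_attempts):
            cand = int(rng.integers(1, len(seq) - seg_len + 2))
            if not _truncates_gene(genes, cand, cand + seg_len - 1):
                s = cand
                break
        if s is None:
            s = int(rng.integers(1, len(seq) - seg_len + 2))
            logger.warning("no gene-preserving placement for %s; splitting genes", kind)
        e = s + seg_len - 1
        if kind == "inversion":
            ev = Event("inversion", s, seg_len, end=e)
        else:
            rem_len = len(seq) - seg_len
            dest = None
            for attempt in range(max_placement_attempts):
                cand = int(rng.integers(1, rem_len + 2))
                # destination must not interrupt a post-excision gene
                post = _liftover_deletion(genes, s, e)
                if not _inside_gene(post, cand):
                    dest = cand
                    break
            if dest is None:
                dest = int(rng.integers(1, rem_len + 2))
            ev = Event("translocation", s, seg_len, end=e, dest=dest)
        seq, genes = apply_event(seq, genes, ev)
        log.events.append(ev)

    return AnnotatedGenome(sid, seq, genes), log


# ---------------------------------------------------------------------------
# Assembly degradation


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    source_start: int  # 1-based offset of the contig in the source genome


def degrade_assembly(
    genome: AnnotatedGenome,
    fragment_mean: float = 20_000,
    dropout_fraction: float = 0.02,
    seed: int = 0,
) -> list[Contig]:
    """Fragment a genome into contigs and drop a fraction of them.

    Cut points follow a Poisson process (exponential spacing with mean
    ``fragment_mean``); each resulting contig is independently discarded
    with probability ``dropout_fraction``. Contigs carry their 1-based
    source offset as provenance.
    """
    if fragment_mean <= 0:
        raise ValueError("fragment_mean must be positive")
    if not (0 <= dropout_fraction < 1):
        raise ValueError("dropout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = len(genome)
    cuts = []
    pos = 0.0
    while True:
        pos += rng.exponential(fragment_mean)
        if pos >= L:
            break
        cuts.append(int(pos))
    bounds = [0] + sorted(set(c for c in cuts if 0 < c < L)) + [L]
    contigs = []
    idx = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        if rng.random() < dropout_fraction:
            continue
        idx += 1
        contigs.append(
            Contig(f"{genome.id}_c{idx:03d}", genome.sequence[s:e], s + 1)
        )
    return contigs


# ---------------------------------------------------------------------------
# Variant table


@dataclass
class VariantTable:
    """Per-sample allele calls at a shared set of SNP sites.

    ``sites`` maps site_id -> reference allele; ``calls`` maps
    sample_id -> {site_id: allele} with missing calls simply absent.
    """

    sites: dict[str, str]
    calls: dict[str, dict[str, str]]

    def __post_init__(self):
        for sample, alleles in self.calls.items():
            for site, a in alleles.items():
                if site not in self.sites:
                    raise ValueError(f"call at unknown site {site} in {sample}")
                if a not in "ACGT":
                    raise ValueError(f"bad allele {a!r} for {sample}@{site}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls)

    def to_tsv(self, path: str | Path) -> None:
        samples = self.sample_ids
        rows = []
        for site, ref in self.sites.items():
            row = {"site_id": site, "ref": ref}
            for s in samples:
                row[s] = self.calls[s].get(site, ".")
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        samples = [c for c in df.columns if c not in ("site_id", "ref")]
        sites = dict(zip(df["site_id"], df["ref"]))
        calls: dict[str, dict[str, str]] = {s: {} for s in samples}
        for _, row in df.iterrows():
            for s in samples:
                a = row[s]
                if isinstance(a, str) and a in "ACGT":
                    calls[s][row["site_id"]] = a
        return cls(sites, calls)


# ---------------------------------------------------------------------------
# Cohort design and simulation


@dataclass
class CohortDesign:
    """Parameters of the synthetic longitudinal twin cohort.

    Defaults reproduce the 46-sample design: two host genotypes of 11
    individuals each, 4 twin pairs per genotype, one individual per
    genotype sampled at 3 timepoints and the rest at 2.
    """

    n_individuals_per_genotype: int = 11
    n_twin_pairs_per_genotype: int = 4
    timepoints_per_individual: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3)
    genotypes: tuple[str, ...] = ("GG", "AA")
    p_twin_share: float = 0.5
    p_persist: float = 0.9
    n_strains: int = 32
    snp_rate: float = 0.005
    indel_rate: float = 5e-4
    n_inversions: int = 2
    n_translocations: int = 1
    genome_length: int = 50_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (500, 1500)
    fragment_mean: float = 20_000.0
    dropout_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("p_twin_share", "p_persist", "dropout_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("snp_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_individuals_per_genotype",
            "n_twin_pairs_per_genotype",
            "n_strains",
            "n_inversions",
            "n_translocations",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 2 * self.n_twin_pairs_per_genotype > self.n_individuals_per_genotype:
            raise ValueError("more twin individuals than individuals per genotype")
        if len(self.timepoints_per_individual) != self.n_individuals_per_genotype:
            raise ValueError(
                "timepoints_per_individual must list one count per individual per genotype"
            )

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * sum(self.timepoints_per_individual)


@dataclass
class CohortResult:
    design: CohortDesign
    metadata: pd.DataFrame  # sample_id individual_id family_id genotype timepoint true_strain_id
    assemblies: dict[str, list[Contig]]
    variants: VariantTable
    strains: dict[str, AnnotatedGenome]
    ancestor: AnnotatedGenome
    event_logs: dict[str, StrainEventLog]


METADATA_COLUMNS = [
    "sample_id",
    "individual_id",
    "family_id",
    "genotype",
    "timepoint",
    "true_strain_id",
]


def simulate_cohort(design: CohortDesign) -> CohortResult:
    """Simulate the full cohort: strains, assignments, assemblies, variants.

    Strain assignment honors ``p_twin_share`` at the twins' first timepoint
    and ``p_persist`` between an individual's consecutive timepoints;
    replacement draws a different strain from the pool uniformly. Fully
    deterministic given ``design.seed``.
    """
    seed = design.seed
    ancestor = generate_reference(
        design.genome_length,
        design.n_genes,
        design.gene_length_range,
        seed=derive_seed(seed, "reference"),
    )
    strains: dict[str, AnnotatedGenome] = {}
    event_logs: dict[str, StrainEventLog] = {}
    for i in range(design.n_strains):
        sid = f"strain_{i + 1:02d}"
        g, log = derive_strain(
            ancestor,
            snp_rate=design.snp_rate,
            indel_rate=design.indel_rate,
            n_inversions=design.n_inversions,
            n_translocations=design.n_translocations,
            seed=derive_seed(seed, "strain", sid),
            strain_id=sid,
        )
        strains[sid] = g
        event_logs[sid] = log
    strain_ids = list(strains)

    rng = rng_for(seed, "assignment")
    # founding strains are handed out without replacement: real cohorts carry
    # individual-specific strains unless transmission (twinship) intervenes
    unassigned = list(rng.permutation(strain_ids))

    def draw_founding() -> str:
        if unassigned:
            return unassigned.pop()
        logger.warning("strain pool exhausted; reusing strains for new individuals")
        return strain_ids[rng.integers(0, len(strain_ids))]

    def draw_other(current: str) -> str:
        others = [s for s in strain_ids if s != current]
        if not others:
            return current
        return others[rng.integers(0, len(others))]

    rows = []
    for genotype in design.genotypes:
        n_ind = design.n_individuals_per_genotype
        n_twin = design.n_twin_pairs_per_genotype
        first_strains: dict[str, str] = {}
        individuals = [f"{genotype}_i{i + 1:02d}" for i in range(n_ind)]
        families = {}
        for j in range(n_twin):
            fam = f"{genotype}_f{j + 1:02d}"
            a, b = individuals[2 * j], individuals[2 * j + 1]
            families[a] = fam
            families[b] = fam
            first_strains[a] = draw_founding()
            if rng.random() < design.p_twin_share:
                first_strains[b] = first_strains[a]
            else:
                first_strains[b] = draw_founding()
        for k, ind in enumerate(individuals[2 * n_twin :]):
            families[ind] = f"{genotype}_f{n_twin + k + 1:02d}"
            first_strains[ind] = draw_founding()
        for ind, n_tp in zip(individuals, design.timepoints_per_individual):
            current = first_strains[ind]
            for tp in range(1, n_tp + 1):
                if tp > 1:
                    if rng.random() >= design.p_persist:
                        current = draw_other(current)
                rows.append(
                    {
                        "sample_id": f"{ind}_t{tp}",
                        "individual_id": ind,
                        "family_id": families[ind],
                        "genotype": genotype,
                        "timepoint": tp,
                        "true_strain_id": current,
                    }
                )
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)

    assemblies = {
        row.sample_id: degrade_assembly(
            replace_id(strains[row.true_strain_id], row.sample_id),
            fragment_mean=design.fragment_mean,
            dropout_fraction=design.dropout_fraction,
            seed=derive_seed(seed, "assembly", row.sample_id),
        )
        for row in metadata.itertuples()
    }

    variants = _build_variant_table(
        ancestor, strains, event_logs, metadata, design.dropout_fraction, seed
    )
    return CohortResult(design, metadata, assemblies, variants, strains, ancestor, event_logs)


def replace_id(genome: AnnotatedGenome, new_id: str) -> AnnotatedGenome:
    return AnnotatedGenome(new_id, genome.sequence, genome.genes)


def _build_variant_table(
    ancestor: AnnotatedGenome,
    strains: dict[str, AnnotatedGenome],
    event_logs: dict[str, StrainEventLog],
    metadata: pd.DataFrame,
    miss_rate: float,
    seed: int,
) -> VariantTable:
    """Variant sites are the union of strain SNP positions on the ancestor.

    A sample's call at a site is its strain's allele there; calls go
    missing independently with probability ``miss_rate``, standing in for
    coverage loss in the degraded assemblies.
    """
    snp_by_strain: dict[str, dict[int, str]] = {}
    for sid, log in event_logs.items():
        snp_by_strain[sid] = {
            ev.position: ev.payload for ev in log.events if ev.type == "snp"
        }
    all_pos = sorted({p for d in snp_by_strain.values() for p in d})
    sites = {f"site_{p:06d}": ancestor.sequence[p - 1] for p in all_pos}
    rng = rng_for(seed, "variants")
    calls: dict[str, dict[str, str]] = {}
    for row in metadata.itertuples():
        strain_snps = snp_by_strain[row.true_strain_id]
        sample_calls = {}
        miss = rng.random(len(all_pos))
        for i, p in enumerate(all_pos):
            if miss[i] < miss_rate:
                continue
            sample_calls[f"site_{p:06d}"] = strain_snps.get(p, ancestor.sequence[p - 1])
        calls[row.sample_id] = sample_calls
    return VariantTable(sites, calls)


# ---------------------------------------------------------------------------
# Writers


def write_cohort(result: CohortResult, outdir: str | Path) -> None:
    """Write all cohort artifacts: FASTAs, GFF3, metadata, variants, events."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(result.ancestor, out / "reference.fasta", out / "reference.gff3")
    asm_dir = out / "assemblies"
    asm_dir.mkdir(exist_ok=True)
    for sample_id, contigs in result.assemblies.items():
        write_fasta(
            asm_dir / f"{sample_id}.fasta",
            {c.contig_id: c.sequence for c in contigs},
        )
    result.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    result.variants.to_tsv(out / "variants.tsv")
    strain_dir = out / "strains"
    strain_dir.mkdir(exist_ok=True)
    for sid, g in result.strains.items():
        write_fasta(strain_dir / f"{sid}.fasta", {sid: g.sequence})
    rows = []
    for sid, log in result.event_logs.items():
        for i, ev in enumerate(log.events):
            rows.append(
                {
                    "strain_id": sid,
                    "parent_id": log.parent_id,
                    "event_index": i,
                    "type": ev.type,
                    "position": ev.position,
                    "length": ev.length,
                    "end": ev.end,
                    "dest": ev.dest,
                    "payload": ev.payload,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "parent_id",
            "event_index",
            "type",
            "position",
            "length",
            "end",
            "dest",
            "payload",
        ],
    ).to_csv(out / "events.tsv", sep="\t", index=False)
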