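"""End-to-end orchestration: simulate -> regions -> synteny -> markers -> stats.

Every stage reads and writes plain-text artifacts (FASTA, GFF3, TSV, JSON)
in a run directory, logs per-stage counts, and is byte-for-byte
reproducible given the run seed (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from syntrack import __version__
from syntrack._seeds import derive_seed
from syntrack.genome import read_fasta, read_genome
from syntrack.markersnp import sharing_table, write_sharing
from syntrack.regions import RegionSearchParams, build_region_set, region_summary, write_region_set
from syntrack.simulate import CohortDesign, VariantTable, simulate_cohort, write_cohort
from syntrack.stats import (
    annotate_pairs,
    category_tests,
    genotype_stability_test,
    mann_whitney,
)
from syntrack.synteny import SyntenyParams, compare_all, comparisons_to_frame, write_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; YAML keys mirror the dataclass fields."""

    seed: int | None = None
    design: CohortDesign = None  # type: ignore[assignment]
    region_params: RegionSearchParams = field(default_factory=RegionSearchParams)
    synteny_params: SyntenyParams = field(default_factory=SyntenyParams)
    n_genes_per_round: int = 5
    n_boot: int = 9999
    alpha: float = 0.05
    aggregate_by_individual: bool = True
    marker_denominator: str = "union"

    def __post_init__(self):
        if self.design is None:
            self.design = CohortDesign(seed=self.seed if self.seed is not None else 0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = raw.get("seed")
        design_kw = dict(raw.get("design", {}))
        if seed is not None:
            design_kw.setdefault("seed", seed)
        for key in ("timepoints_per_individual", "genotypes", "gene_length_range"):
            if key in design_kw:
                design_kw[key] = tuple(design_kw[key])
        cfg = cls(
            seed=seed,
            design=CohortDesign(**design_kw),
            region_params=RegionSearchParams(**raw.get("region_params", {})),
            synteny_params=SyntenyParams(**raw.get("synteny_params", {})),
        )
        for key in (
            "n_genes_per_round",
            "n_boot",
            "alpha",
            "aggregate_by_individual",
            "marker_denominator",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "design": dataclasses.asdict(self.design),
            "region_params": dataclasses.asdict(self.region_params),
            "synteny_params": dataclasses.asdict(self.synteny_params),
            "n_genes_per_round": self.n_genes_per_round,
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "aggregate_by_individual": self.aggregate_by_individual,
            "marker_denominator": self.marker_denominator,
        }


def _setup_run_logging(outdir: Path) -> None:
    """Stage-granularity log file; deliberately no timestamps so reruns
    with the same seed are byte-identical."""
    root = logging.getLogger("syntrack")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):
        if getattr(h, "_syntrack_run", False):
            root.removeHandler(h)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler._syntrack_run = True  # type: ignore[attr-defined]
    root.addHandler(handler)


# ---------------------------------------------------------------------------
# Stages


def run_simulate(config: RunConfig, outdir: str | Path, overwrite: bool = False):
    if config.seed is None:
        raise ValueError("a seed is mandatory for simulation")
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite to replace")
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out)
    design = dataclasses.replace(config.design, seed=config.seed)
    result = simulate_cohort(design)
    write_cohort(result, out)
    logger.info(
        "simulate: %d samples, %d individuals, %d strains, %d variant sites",
        len(result.metadata),
        result.metadata["individual_id"].nunique(),
        len(result.strains),
        len(result.variants.sites),
    )
    return result


def load_cohort_dir(outdir: str | Path):
    """Read reference, assemblies, metadata and variants back from disk."""
    out = Path(outdir)
    reference = read_genome(out / "reference.fasta", out / "reference.gff3")
    metadata = pd.read_csv(out / "metadata.tsv", sep="\t")
    assemblies = {}
    for row in metadata.itertuples():
        fasta = out / "assemblies" / f"{row.sample_id}.fasta"
        assemblies[row.sample_id] = list(read_fasta(fasta).items())
    variants = VariantTable.from_tsv(out / "variants.tsv")
    return reference, assemblies, metadata, variants


def run_select_regions(config: RunConfig, outdir: str | Path, reference=None, assemblies=None):
    out = Path(outdir)
    if reference is None or assemblies is None:
        reference, assemblies, _, _ = load_cohort_dir(out)
    region_set = build_region_set(
        reference,
        assemblies,
        config.region_params,
        seed=derive_seed(config.seed or 0, "regions"),
        n_genes_per_round=config.n_genes_per_round,
    )
    write_region_set(region_set, out)
    tried = sum(len(r["genes_tried"]) for r in region_set.rounds)
    logger.info(
        "select-regions: %d gene(s) tried over %d round(s); %d region(s) kept%s",
        tried,
        len(region_set.rounds),
        len(region_set.regions),
        "" if region_set.complete else " (INCOMPLETE: below min_regions)",
    )
    return region_set


def run_synteny(config: RunConfig, outdir: str | Path, region_set):
    out = Path(outdir)
    comparisons = compare_all(region_set, config.synteny_params)
    write_scores(comparisons, out / "synteny_scores.tsv")
    n_undef = sum(1 for c in comparisons if c.score is None)
    logger.info(
        "synteny: %d comparison(s) across %d region(s); %d undefined (zero blocks)",
        len(comparisons),
        len(getattr(region_set, "regions", region_set)),
        n_undef,
    )
    return comparisons


def run_markersnp(config: RunConfig, outdir: str | Path, variants, metadata):
    out = Path(outdir)
    df = sharing_table(variants, metadata, denominator=config.marker_denominator)
    write_sharing(df, out / "marker_snp_sharing.tsv")
    logger.info("markersnp: %d pairwise sharing value(s)", len(df))
    return df


def run_stats(config: RunConfig, outdir: str | Path, metric_tables: dict[str, pd.DataFrame], metadata):
    """Category tests + genotype tests + Table-2-style summary grid.

    ``metric_tables`` maps metric name -> (sample_a, sample_b, value) frame.
    """
    out = Path(outdir)
    all_tests = []
    grid_rows = []
    for metric, values in metric_tables.items():
        ann = annotate_pairs(values, metadata)
        tests = category_tests(
            ann,
            n_boot=config.n_boot,
            seed=derive_seed(config.seed or 0, "boot", metric),
        )
        tests.insert(0, "metric", metric)
        all_tests.append(tests)
        intra = ann[ann["category"] == "intraindividual"].copy()
        meta_ind = metadata.set_index("sample_id")["individual_id"]
        intra["individual_id"] = intra["sample_a"].map(meta_ind)
        geno_p = genotype_stability_test(
            intra[intra["genotype"] != "mixed"],
            aggregate_by_individual=config.aggregate_by_individual,
        )
        grid_rows.append(_grid_row(metric, tests, geno_p, config.alpha))
    tests_df = pd.concat(all_tests, ignore_index=True)
    tests_df.to_csv(out / "category_tests.tsv", sep="\t", index=False, float_format="%.6g")
    grid = pd.DataFrame(grid_rows)
    grid.to_csv(out / "summary_grid.tsv", sep="\t", index=False, float_format="%.4g")
    for row in grid_rows:
        logger.info(
            "stats[%s]: longitudinal stability: %s (p=%s); twin effect: %s (p=%s); "
            "genotype effect: %s (p=%s)",
            row["metric"],
            row["longitudinal_stability"],
            row["stability_p"],
            row["twin_effect"],
            row["twin_p"],
            row["genotype_effect"],
            row["genotype_p"],
        )
    return tests_df, grid


def _fmt_p(p) -> float | str:
    return "NA" if p is None or (isinstance(p, float) and np.isnan(p)) else float(p)


def _grid_row(metric: str, tests: pd.DataFrame, geno_p: float, alpha: float) -> dict:
    def lookup(a, b):
        row = tests[(tests["category_a"] == a) & (tests["category_b"] == b)]
        return row.iloc[0] if len(row) else None

    stab = lookup("intraindividual", "unrelated")
    twin = lookup("same_family", "unrelated")

    def verdict(row):
        if row is None or row["na"] or np.isnan(row["mean_p"]):
            return "NA", np.nan
        yes = row["mean_p"] < alpha and row["mean_a"] > row["mean_b"]
        return ("yes" if yes else "no"), row["mean_p"]

    stab_v, stab_p = verdict(stab)
    twin_v, twin_p = verdict(twin)
    if np.isnan(geno_p):
        geno_v = "NA"
    else:
        geno_v = "yes" if geno_p < alpha else "no"
    return {
        "metric": metric,
        "longitudinal_stability": stab_v,
        "stability_p": _fmt_p(stab_p),
        "twin_effect": twin_v,
        "twin_p": _fmt_p(twin_p),
        "genotype_effect": geno_v,
        "genotype_p": _fmt_p(geno_p),
    }


def run_full(config: RunConfig, outdir: str | Path, overwrite: bool = False) -> dict:
    """Run every stage, write all artifacts, return the summary manifest."""
    out = Path(outdir)
    cohort = run_simulate(config, out, overwrite=overwrite)
    region_set = run_select_regions(
        config, out, reference=cohort.ancestor, assemblies=cohort.assemblies
    )
    comparisons = run_synteny(config, out, region_set)
    scores = comparisons_to_frame(comparisons).rename(columns={"score": "value"})
    sharing = run_markersnp(config, out, cohort.variants, cohort.metadata)
    metric_tables = {
        "synteny_score": scores[["sample_a", "sample_b", "value"]].dropna(),
        "percent_marker_snps_shared": sharing.rename(
            columns={"percent_shared": "value"}
        )[["sample_a", "sample_b", "value"]].dropna(),
    }
    tests_df, grid = run_stats(config, out, metric_tables, cohort.metadata)
    manifest = {
        "tool": "syntrack",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {
            "samples": int(len(cohort.metadata)),
            "regions_kept": len(region_set.regions),
            "regions_complete": bool(region_set.complete),
            "comparisons": int(len(comparisons)),
            "undefined_comparisons": int(sum(1 for c in comparisons if c.score is None)),
        },
        "summary": grid.to_dict(orient="records"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary_md(out, manifest, tests_df)
    return manifest


def _write_summary_md(out: Path, manifest: dict, tests_df: pd.DataFrame) -> None:
    lines = ["# Run summary", ""]
    c = manifest["counts"]
    lines.append(
        f"Samples: {c['samples']}; regions kept: {c['regions_kept']} "
        f"(complete: {c['regions_complete']}); pairwise comparisons: {c['comparisons']} "
        f"({c['undefined_comparisons']} undefined)."
    )
    lines.append("")
    for row in manifest["summary"]:
        lines.append(
            f"- **{row['metric']}** — longitudinal stability: {row['longitudinal_stability']} "
            f"(p={row['stability_p']}); twin effect: {row['twin_effect']} "
            f"(p={row['twin_p']}); genotype effect: {row['genotype_effect']} "
            f"(p={row['genotype_p']})"
        )
    lines.append("")
    (out / "summary.md").write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Two-clade validation scenario


def validate_clades(
    seed: int,
    outdir: str | Path | None = None,
    n_genomes: int = 15,
    n_genes: int = 5,
    flank: int = 10_000,
    genome_length: int = 80_000,
    n_reference_genes: int = 40,
) -> dict:
    """Two-clade discrimination check on synthetic genomes.

    Simulates ``n_genomes`` genomes in two clades whose founders differ by
    more rearrangements than members within a clade, retrieves ``n_genes``
    regions with wide (10 kb) flanks, and tests within-clade vs
    between-clade synteny scores with a rank-sum test. The prevalence
    threshold is relaxed to two-thirds of the genomes (15 genomes cannot
    clear a '>15 samples' filter by construction).
    """
    from syntrack.simulate import derive_strain, generate_reference

    ancestor = generate_reference(
        genome_length, n_reference_genes, seed=derive_seed(seed, "clade-ref")
    )
    founders = {}
    for clade in ("A", "B"):
        founders[clade], _ = derive_strain(
            ancestor,
            snp_rate=0.005,
            indel_rate=5e-4,
            n_inversions=4,
            n_translocations=2,
            seed=derive_seed(seed, "founder", clade),
            strain_id=f"clade{clade}",
        )
    sizes = {"A": (n_genomes + 1) // 2, "B": n_genomes // 2}
    genomes = {}
    clade_of = {}
    for clade, size in sizes.items():
        for i in range(size):
            gid = f"{clade}{i + 1:02d}"
            g, _ = derive_strain(
                founders[clade],
                snp_rate=0.002,
                indel_rate=2e-4,
                n_inversions=1,
                n_translocations=0,
                seed=derive_seed(seed, "member", gid),
                strain_id=gid,
            )
            genomes[gid] = g
            clade_of[gid] = clade
    assemblies = {gid: [(gid, g.sequence)] for gid, g in genomes.items()}
    params = RegionSearchParams(
        flank=flank,
        min_prevalence=(2 * n_genomes) // 3,
        min_regions=3,
    )
    region_set = build_region_set(
        ancestor,
        assemblies,
        params,
        seed=derive_seed(seed, "clade-regions"),
        n_genes_per_round=n_genes,
    )
    comparisons = compare_all(region_set, SyntenyParams())
    within, between = [], []
    for c in comparisons:
        if c.score is None:
            continue
        (within if clade_of[c.sample_a] == clade_of[c.sample_b] else between).append(c.score)
    p = mann_whitney(within, between)
    result = {
        "n_regions": len(region_set.regions),
        "n_within": len(within),
        "n_between": len(between),
        "within_mean": float(np.mean(within)),
        "between_mean": float(np.mean(between)),
        "rank_sum_p": float(p),
    }
    logger.info(
        "validate-clades: %d regions; within mean %.4f vs between mean %.4f (p=%.3g)",
        result["n_regions"],
        result["within_mean"],
        result["between_mean"],
        result["rank_sum_p"],
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_scores(comparisons, out / "clade_synteny_scores.tsv")
        with open(out / "clade_validation.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
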