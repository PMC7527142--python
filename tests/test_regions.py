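import itertools

import numpy as np
import pytest

from syntrack.genome import revcomp
from syntrack.regions import (
    RegionHit,
    RegionSearchParams,
    build_region_set,
    extract_flanked_region,
    search_gene,
    select_candidate_genes,
)
from syntrack.simulate import generate_reference

from conftest import mutate_snps, random_dna


@pytest.fixture(scope="module")
def ref40():
    return generate_reference(50_000, 40, (500, 1500), seed=3)


class TestSelectCandidateGenes:
    def test_gap_constraint_holds(self, ref40):
        ids = select_candidate_genes(ref40, 5, min_gene_gap=5, seed=1)
        index = {g.gene_id: i for i, g in enumerate(ref40.genes)}
        picks = sorted(index[g] for g in ids)
        assert len(picks) == 5
        for a, b in itertools.combinations(picks, 2):
            assert abs(a - b) >= 6  # >= 5 intervening genes

    def test_infeasible_names_max(self):
        g = generate_reference(20_000, 10, (300, 800), seed=4)
        # brute force: max subsets of {0..9} with pairwise distance >= 6 is 2
        feasible = max(
            len(s)
            for r in range(1, 11)
            for s in itertools.combinations(range(10), r)
            if all(b - a >= 6 for a, b in zip(s, s[1:]))
        )
        assert feasible == 2
        with pytest.raises(ValueError, match="maximum feasible n is 2"):
            select_candidate_genes(g, 3, min_gene_gap=5, seed=1)

    def test_zero_gap_plain_sample(self, ref40):
        ids = select_candidate_genes(ref40, 10, min_gene_gap=0, seed=2)
        assert len(set(ids)) == 10

    def test_deterministic(self, ref40):
        assert select_candidate_genes(ref40, 5, 5, seed=9) == select_candidate_genes(
            ref40, 5, 5, seed=9
        )

    def test_exclusions_respected(self, ref40):
        first = select_candidate_genes(ref40, 3, 5, seed=1)
        second = select_candidate_genes(ref40, 3, 5, seed=2, exclude=set(first))
        assert not set(first) & set(second)


class TestSearchGene:
    def test_exact_substring_perfect_hit(self):
        rng = np.random.default_rng(0)
        gene = random_dna(rng, 900)
        contig = random_dna(rng, 3000) + gene + random_dna(rng, 3000)
        hit = search_gene(gene, [("c1", contig)], sample_id="s")
        assert hit is not None
        assert hit.identity == 1.0 and hit.coverage == 1.0
        assert (hit.start, hit.end) == (3001, 3900)
        assert hit.strand == "+"

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(1)
        gene = random_dna(rng, 900)
        contig = random_dna(rng, 1000) + revcomp(gene) + random_dna(rng, 1000)
        hit = search_gene(gene, [("c1", contig)])
        assert hit is not None and hit.strand == "-"
        assert (hit.start, hit.end) == (1001, 1900)

    def test_five_percent_divergence_rejected(self):
        rng = np.random.default_rng(2)
        gene = random_dna(rng, 1000)
        mutated = mutate_snps(rng, gene, 50)  # 5% substituted -> identity ~0.95
        contig = random_dna(rng, 1000) + mutated + random_dna(rng, 1000)
        assert search_gene(gene, [("c1", contig)]) is None
        # alignment oracle: the same hit passes a relaxed identity threshold
        relaxed = RegionSearchParams(min_identity=0.90)
        hit = search_gene(gene, [("c1", contig)], relaxed)
        assert hit is not None
        assert 0.93 <= hit.identity <= 0.97

    def test_partial_gene_at_contig_edge_rejected(self):
        rng = np.random.default_rng(3)
        gene = random_dna(rng, 1000)
        contig = gene[:800] + ""  # only the first 80% present
        contig = random_dna(rng, 500) + gene[:800]
        assert search_gene(gene, [("c1", contig)]) is None

    def test_empty_assembly_absent(self):
        rng = np.random.default_rng(4)
        assert search_gene(random_dna(rng, 500), []) is None

    def test_contig_order_invariance(self):
        rng = np.random.default_rng(5)
        gene = random_dna(rng, 800)
        c1 = random_dna(rng, 2000) + gene + random_dna(rng, 500)
        c2 = random_dna(rng, 4000)
        h1 = search_gene(gene, [("c1", c1), ("c2", c2)])
        h2 = search_gene(gene, [("c2", c2), ("c1", c1)])
        assert (h1.contig_id, h1.start, h1.end) == (h2.contig_id, h2.start, h2.end)


class TestExtractFlankedRegion:
    def _assembly(self, rng, contig_len=20_000):
        return [("c1", random_dna(rng, contig_len))]

    def test_flank_arithmetic(self):
        rng = np.random.default_rng(6)
        asm = self._assembly(rng)
        hit = RegionHit("s", "c1", 5001, 6000, "+", 1.0, 1.0)
        out = extract_flanked_region(hit, asm, flank=3500)
        assert len(out.sequence) == 8000  # 1501..9500
        assert out.sequence == asm[0][1][1500:9500]
        assert out.clipped_left == 0 and out.clipped_right == 0

    def test_left_clip(self):
        rng = np.random.default_rng(7)
        asm = self._assembly(rng)
        hit = RegionHit("s", "c1", 100, 1099, "+", 1.0, 1.0)
        out = extract_flanked_region(hit, asm, flank=3500)
        assert out.clipped_left == 3500 - 99
        assert len(out.sequence) == 99 + 1000 + 3500

    def test_minus_strand_reverse_complement(self):
        rng = np.random.default_rng(8)
        asm = self._assembly(rng)
        hit = RegionHit("s", "c1", 5001, 6000, "-", 1.0, 1.0)
        out = extract_flanked_region(hit, asm, flank=1000)
        plus = extract_flanked_region(
            RegionHit("s", "c1", 5001, 6000, "+", 1.0, 1.0), asm, flank=1000
        )
        assert out.sequence == revcomp(plus.sequence)


class TestBuildRegionSet:
    def test_identical_assemblies_keep_all(self):
        g = generate_reference(35_000, 40, (300, 800), seed=9)
        assemblies = {f"s{i:02d}": [("c1", g.sequence)] for i in range(20)}
        params = RegionSearchParams(flank=1000, min_prevalence=16, min_regions=4)
        rs = build_region_set(g, assemblies, params, seed=1, n_genes_per_round=5)
        assert rs.complete
        assert len(rs.regions) == 5
        for hits in rs.regions.values():
            assert len(hits) == 20
            assert all(h.identity == 1.0 and h.coverage == 1.0 for h in hits.values())

    def test_too_few_assemblies_empty_flagged(self):
        g = generate_reference(20_000, 20, (300, 800), seed=10)
        assemblies = {f"s{i}": [("c1", g.sequence)] for i in range(10)}
        params = RegionSearchParams(flank=500, min_prevalence=16, max_iterations=2)
        rs = build_region_set(g, assemblies, params, seed=1)
        assert rs.regions == {}
        assert not rs.complete

    def test_prevalence_is_strict(self):
        # a region in exactly 15 of 20 samples must be dropped (">15 samples")
        g = generate_reference(20_000, 20, (300, 800), seed=11)
        rng = np.random.default_rng(0)
        assemblies = {}
        for i in range(20):
            if i < 15:
                assemblies[f"s{i:02d}"] = [("c1", g.sequence)]
            else:
                assemblies[f"s{i:02d}"] = [("c1", random_dna(rng, 20_000))]
        params = RegionSearchParams(flank=500, min_prevalence=16, max_iterations=1)
        rs = build_region_set(g, assemblies, params, seed=1, n_genes_per_round=3)
        assert rs.regions == {}

    def test_retained_hits_satisfy_thresholds(self, small_cohort):
        params = RegionSearchParams(min_prevalence=10, min_regions=3, flank=2000)
        rs = build_region_set(
            small_cohort.ancestor, small_cohort.assemblies, params, seed=2, n_genes_per_round=3
        )
        assert rs.regions
        for hits in rs.regions.values():
            assert len(hits) >= 10
            for h in hits.values():
                assert h.identity >= params.min_identity
                assert h.coverage >= params.min_coverage
                assert len(h.sequence) <= (h.end - h.start + 1) + 2 * params.flank
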