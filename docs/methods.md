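# Methods

This note documents the models and procedures implemented in `syntrack`,
the defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that matter.

## Synteny blocks and the synteny score

Two homologous regions are decomposed into synteny blocks: maximal
collinear stretches of shared sequence on either strand. A *break* is a
nonhomologous stretch longer than `max_gap` (default 15 bp) on **either**
sequence, or a strand change. Consequences worth spelling out:

- Isolated substitutions do not break blocks: a lone SNP creates a 1-bp
  nonhomologous stretch, far below 15 bp. Clustered substitutions whose
  joint span exceeds 15 bp do break. So, at the divergence levels the
  region-selection thresholds admit (≥ 97% identity), the score responds
  mostly to structural differences — which is the point of the method.
- Indels up to 15 bp are bridged; longer ones break.
- Inverted segments count as ordinary blocks toward `n` and `Σ Lsb`
  (configurable via `count_inverted_blocks`; the alternative treats them
  as breaks). Either way an inversion adds breaks at its boundaries.

The score of a comparison with `n ≥ 1` blocks is
`1 + log10(Σ Lsb / (Lseq · n))`, where `Lseq` is the length of the shorter
sequence and block lengths are measured on the shorter-sequence side,
clamped so `Σ Lsb ≤ Lseq`. Hence `score ≤ 1`, with equality exactly for a
single block covering the shorter sequence. `n = 0` (no detectable
homology) yields *undefined*, not −∞; undefined pairs are excluded from
statistics and counted in the log.

### Block finding

Anchors are exact shared k-mers (default `k = 13`) on both strands,
suppressed when a k-mer occurs more than 8 times on a side (repeats).
Anchors on one diagonal merge into runs; runs merge across nearby
diagonals when the intervening nonhomologous stretch is ≤ `max_gap` on
both sequences. Conflicting claims (overlap > k on either axis) are
resolved by weighted interval scheduling on anchored coverage, with exact
dynamic programming on the a-axis and a greedy pass on the b-axis. The
minimum reportable block is `2k` (a chain of at least two anchors), which
suppresses chance k-mer hits: two unrelated random 8-kb sequences share
≈ 1 k-mer at `k = 13` and yield zero blocks. A brute-force oracle
(exhaustive subset search over transitively merged seed chains) agrees
with this chainer within ±1 block and ±2k coverage on constructed cases;
boundary placement is accurate to about one k-mer.

Identical sequences short-circuit to a single full block, and in cohort
comparisons each unique extracted sequence pair is compared once (samples
carrying the same strain often contribute identical regions).

## Region selection

Query genes are sampled uniformly from the reference annotation subject to
≥ `min_gene_gap` (default 5) intervening genes between any two picks, so
regions cannot overlap. Each gene is searched in every sample assembly by
seed-and-extend homology search: exact 15-mer seeding on both strands,
then local alignment of the query against the seeded window
(match +1, mismatch −2, gap open −4, gap extend −1, via Biopython's
PairwiseAligner). A hit needs identity ≥ 0.97 (matches / alignment
columns) and coverage ≥ 0.90 (aligned query bases / query length); the
best hit per sample maximizes identity × coverage, with ties broken by
longer alignment, then lexicographically smaller contig id, then leftmost
position — making the result invariant to contig order. Multi-copy hits
above threshold are resolved to the single best (the comparison needs one
region per sample); this resolution and the retention of edge-clipped
regions are deliberate choices where the procedure is underdetermined —
clipping is absorbed naturally by `Lseq` in the score.

Hits are extended by `flank` (default 3500 bp) on each side, clipped at
contig ends, reverse-complemented to query orientation for minus-strand
hits. Regions found in fewer than `min_prevalence` samples (default 16,
i.e., strictly more than 15) are dropped; selection iterates with fresh
genes — never reusing tried ones, still honoring gaps against kept genes —
until `min_regions` (default 4) survive, the pool is exhausted, or
`max_iterations` rounds have run. An under-filled region set is returned
flagged, not raised.

## Marker-SNPs

The pool takes each individual's first sample. A marker for pool sample
`s` is a (site, allele) where `s`'s call differs from every other pool
sample's call; a missing call elsewhere does not veto uniqueness (and a
sample with a missing call cannot gain a marker there). All samples are
then evaluated against the pooled marker list using their own calls, and
pairwise sharing is `100 · |A ∩ B| / |A ∪ B|`. The union denominator makes
identical samples score 100%; the literal sum denominator (`|A| + |B|`,
which caps identical samples at 50%) is available via
`denominator="sum"`. An empty union is undefined and excluded. Note a
structural property, faithful to the pool definition: when two pool
samples carry the same strain, neither gets markers at the sites that
distinguish that strain — so twin pairs sharing a strain are largely
invisible to this statistic, whereas the synteny score sees them. This
matches the known relative sensitivity of the two approaches.

## Category statistics

The three categories (intraindividual / same family / unrelated) partition
all C(S, 2) sample pairs. Differences are tested with a subsampled
bootstrapped Wilcoxon rank-sum test: per replicate the larger category is
subsampled without replacement to the smaller category's size and a
two-sided rank-sum test is run; the mean p over replicates is primary and
the median is recorded (both conventions exist in the literature;
`n_boot` defaults to 9999 with 999 in common use). The subsampling unit is
the pairwise comparison value — well defined for all three categories —
rather than the individual. Results are flagged NA when a category has 3
or fewer values. The single-test kernel uses exact enumeration for
tie-free samples with ≤ 12 total observations, otherwise the normal
approximation with tie and continuity corrections; two identical samples
give p = 1.

Calibration, measured under the null: the mean-p statistic is
conservative, increasingly so with group-size imbalance (averaging
correlated replicate p-values shrinks the tails): null rejection at
α = 0.05 is ≈ 5.8% at equal sizes, ≈ 3% at 26 vs 32 (the default cohort's
intra vs same-family counts), ≈ 1% at 20 vs 60. It never exceeds the
nominal level, so significance calls are, if anything, understated.

Host-genotype effects on stability are tested by a plain rank-sum test of
intraindividual values between genotypes, by default after averaging
within individuals (testing mean intraindividual similarity; the
unaggregated mode is available). `subsampled_spearman` balances unequal
groups before correlating: per permutation it draws `n_sub` (default 15)
members per group without replacement and computes Spearman's rho on the
pool, reporting the mean over `n_perm` (default 999) permutations.

## The simulator: what it emulates, and what it does not

One ancestral genome per simulated species; strains are its descendants
(a star phylogeny), diverged by per-bp SNPs (default 0.005 — pairwise gene
identity ≈ 99%, comfortably above the 97% search threshold), geometric
indels (rate 5 × 10⁻⁴/bp, mean 3 bp), and per-strain 2 inversions + 1
translocation of 0.5–3 kb segments that avoid truncating genes when a
placement allows (100 attempts, then a logged forced split). Every event
is logged with coordinates valid at application time; replaying the log on
the parent reproduces the strain byte-for-byte, and gene coordinates are
lifted over through every event.

Cohort structure follows the default design: 2 genotypes × 11 individuals,
4 twin pairs per genotype, 20 individuals with 2 timepoints and 2 with 3
(46 samples). Founding strains are assigned **without replacement** from a
pool of 32: real cohort members carry individual-specific strains unless
transmission intervenes, and a with-replacement draw from a small pool
would force unrelated individuals to share strains — which both distorts
the unrelated-category baseline and annihilates marker-SNPs (a marker must
be unique within the pool). Twins share their founding strain with
probability `p_twin_share` (default 0.5); a strain persists between
consecutive timepoints with probability `p_persist` (default 0.9), and
replacement draws a different strain uniformly from the pool. The
replacement model is a stated assumption — real strain-replacement
dynamics are not characterized — not an inference.

Assemblies are the strain genome cut by a Poisson process (mean fragment
20 kb) with each contig independently dropped at 2%, carrying provenance
offsets. The variant table lists every strain SNP position on ancestor
coordinates; a sample's call is its strain's allele, going missing
independently at the dropout rate. This independence is a simplification:
the variant channel stands in for read-mapped SNP calls from an external
pipeline, not for genotypes derived from our own degraded assemblies.

Not emulated: read-level sequencing (errors, quality scores), capture
hybridization, real assembler behavior (misassembly, collapsed repeats),
within-host strain mixtures, recombination between strains, and realistic
genome scale — the default ancestor is 50 kb with 40 genes, not a 2.3-Mb
bacterial chromosome. Rates are per-bp, so the statistics are scale-free,
but runtime-scaled simulations mean a green recovery test establishes
correctness of the *procedure* on the stated world, not power on real
data.

A seed is mandatory for simulation; per-operation seeds are derived from
the global seed by stable hashing of (seed, purpose, id), so runs are
reproducible and order-independent. Re-running any stage with the same
config and seed reproduces every output file byte-for-byte (no timestamps
are written, including in the run log).

## Two-clade validation scenario

`validate-clades` simulates 15 genomes in two clades: two founders derived
from one ancestor with 4 inversions + 2 translocations each, members
derived from their founder with light divergence (1 inversion,
SNP rate 0.002). Five query genes with 10-kb flanks are retrieved and all
pairwise synteny scores computed; within-clade scores should exceed
between-clade scores by rank-sum test. Since a ">15 samples" prevalence
filter cannot be met by 15 genomes, this scenario relaxes prevalence to
two-thirds of the genomes and requires 3 regions — mirroring a validation
design in which only a subset of regions is recoverable in both clades.

## Known limitations

- Block boundaries are resolved only to about one k-mer (±13 bp); block
  counts can differ by one from an exhaustive decomposition near
  configurable minimum-length and gap thresholds.
- The homology search is tuned for the ≥ 97% identity regime; it is not a
  general-purpose aligner and has a documented floor of ~100 bp queries.
- The bootstrap mean-p is conservative under strong imbalance (see
  calibration above); treat borderline p-values accordingly.
- Circular chromosomes are represented linearly; rearrangements never
  span the origin.
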