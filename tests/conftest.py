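import numpy as np
import pytest

from syntrack.simulate import CohortDesign, simulate_cohort

# scaled-down cohort for unit tests: 8 individuals, 16 samples, 20 kb genome
SMALL_DESIGN = dict(
    n_individuals_per_genotype=4,
    n_twin_pairs_per_genotype=1,
    timepoints_per_individual=(2, 2, 2, 2),
    n_strains=12,
    genome_length=20_000,
    n_genes=20,
    gene_length_range=(300, 800),
    fragment_mean=12_000.0,
    dropout_fraction=0.02,
)


def make_small_design(seed=5, **overrides):
    kw = dict(SMALL_DESIGN)
    kw.update(overrides)
    return CohortDesign(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(make_small_design())


@pytest.fixture(scope="session")
def default_cohort():
    """The full 46-sample design (shared across tests; ~0.3 s to build)."""
    return simulate_cohort(CohortDesign(seed=1))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_snps(rng: np.random.Generator, seq: str, n_snps: int) -> str:
    out = list(seq)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in rng.choice(len(seq), size=n_snps, replace=False):
        out[p] = flip[out[p]]
    return "".join(out)
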