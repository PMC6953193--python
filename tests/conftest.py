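import numpy as np
import pytest

from wildcomp.simulate import (
    SimulationSpec,
    simulate_genome_pair,
    simulate_reads,
)

# small two-genotype study reused across modules (module-level cache via
# session-scoped fixtures; everything is deterministic in the seed)

SMALL_SPEC = SimulationSpec(
    seed=42,
    n_scaffolds=2,
    scaffold_length=120_000,
    n_genes=30,
    gene_length=900,
    intergenic_length=2_500,
    snv_rate=0.003,
    pericentromere_interval=(40_000, 80_000),
    pericentromere_multiplier=3.0,
    n_specific_A=3,
    n_specific_B=3,
    read_depth=10.0,
    read_error_rate=0.0,
)


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def simulated_pair(small_spec):
    return simulate_genome_pair(small_spec)


@pytest.fixture(scope="session")
def simulated_reads(simulated_pair, small_spec):
    genome_a, genome_b, _ = simulated_pair
    return simulate_reads(genome_a, small_spec), simulate_reads(genome_b, small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def mutate_sequence(
    rng: np.random.Generator, seq: str, n_changes: int, keep_tail: int = 0
) -> str:
    """Plant exactly n substitutions at distinct random positions.

    With ``keep_tail`` the last bases stay untouched, guaranteeing an exact
    seed word survives for seeded aligners.
    """
    span = len(seq) - keep_tail
    pos = rng.choice(span, size=min(n_changes, span), replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
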