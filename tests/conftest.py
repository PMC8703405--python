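import numpy as np
import pytest

from mosaicpaint.simulate import (
    SimConfig,
    fragment_to_scaffolds,
    genome_to_str,
    simulate_founders,
    simulate_offspring,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Two 100 kb chromosomes: fast enough for per-module unit tests."""
    return SimConfig(
        n_chrom=2,
        chrom_len=100_000,
        min_segment_len=20_000,
        mean_segment_len=30_000,
        scaffold_len_mean=10_000,
        scaffold_len_sd=5_000,
        scaffold_error_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(cfg, founders, offspring genome, truth, scaffolds, scaffold truth)."""
    founders = simulate_founders(small_cfg)
    offspring, truth = simulate_offspring(founders, small_cfg)
    scaffolds, scf_truth = fragment_to_scaffolds(offspring, small_cfg)
    return small_cfg, founders, offspring, truth, scaffolds, scf_truth


@pytest.fixture(scope="session")
def random_genome():
    """One deterministic 40 kb random chromosome pair for planting tests."""
    rng = np.random.default_rng(1234)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        f"chr{i}": bases[rng.integers(0, 4, 40_000)].tobytes().decode()
        for i in (1, 2)
    }
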