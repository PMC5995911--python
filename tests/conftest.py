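import numpy as np
import pandas as pd
import pytest

import poised as ps


def per_base_mask(intervals, length: int) -> np.ndarray:
    """Brute-force per-base coverage oracle for a single toy chromosome."""
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return mask


def random_toy_intervals(rng, n=50, length=1000, max_len=80):
    """Random (start, end) pairs on a toy chromosome."""
    starts = rng.integers(0, length - 1, n)
    lens = rng.integers(1, max_len, n)
    return [(int(s), int(min(s + l, length))) for s, l in zip(starts, lens)]


@pytest.fixture(scope="session")
def sim_default():
    """One default-scenario simulation shared by the slower tests."""
    cfg = ps.SimulationConfig(seed=11)
    tags, truth = ps.simulate_tags(cfg)
    return cfg, tags, truth


@pytest.fixture(scope="session")
def sim_small():
    """A reduced scenario for peak-calling and pipeline tests."""
    cfg = ps.SimulationConfig(
        seed=5,
        n_genes={"active": 40, "bivalent_other": 10, "bivalent_up": 5, "silent": 5},
        n_chroms=1,
        chrom_length=2_000_000,
    )
    tags, truth = ps.simulate_tags(cfg)
    return cfg, tags, truth


@pytest.fixture()
def toy_promoters():
    genes = [
        ps.GeneModel("g1", "chr1", "+", 10_000),
        ps.GeneModel("g2", "chr1", "-", 30_000),
        ps.GeneModel("g3", "chr2", "+", 5_000),
    ]
    return genes, ps.promoter_windows(genes, width=2000)
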