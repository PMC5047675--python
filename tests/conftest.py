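import numpy as np
import pandas as pd
import pytest

import regulomics as rg


def random_peakset(rng: np.random.Generator, n: int, factor: str = "X",
                   chroms: tuple[str, ...] = ("chr1", "chr2"), span: int = 100_000) -> rg.PeakSet:
    """Random scored intervals for oracle-equivalence tests."""
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(50, 800, size=n)
    df = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"{factor}_{i}" for i in range(n)],
            "score": rng.random(n) * 10,
        }
    )
    return rg.PeakSet(factor, "r1", df)


@pytest.fixture(scope="session")
def sim_config() -> rg.SimConfig:
    return rg.SimConfig(seed=7)


@pytest.fixture(scope="session")
def genome(sim_config) -> rg.GeneAnnotation:
    return rg.make_genome(sim_config)


@pytest.fixture(scope="session")
def peak_replicates(sim_config, genome):
    return rg.simulate_peak_replicates(genome, sim_config)


@pytest.fixture(scope="session")
def mark_tracks(sim_config, genome):
    return rg.simulate_signal(genome, None, sim_config)
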