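import numpy as np
import pandas as pd
import pytest

from promtile import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def experiment():
    """One full synthetic experiment at the default study conditions."""
    return simulate_experiment(SimulationConfig(n_genes=200, genome_seed=1))


@pytest.fixture(scope="session")
def small_experiment():
    """A small experiment for fast structural checks."""
    return simulate_experiment(SimulationConfig(n_genes=30, genome_seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_probe_table(signals, gene_id="gX", spacing=205, chrom="chr1", start0=0):
    """Minimal position-sorted probe table for enrichment-calling tests."""
    n = len(signals)
    starts = start0 + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "probe_id": [f"{gene_id}_p{i:02d}" for i in range(n)],
            "gene_id": gene_id,
            "chrom": chrom,
            "start": starts,
            "end": starts + 60,
            "smoothed": np.asarray(signals, dtype=float),
        }
    )
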