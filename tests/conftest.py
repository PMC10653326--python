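import numpy as np
import pandas as pd
import pytest

from metacomm.simulate import (
    SimulationConfig,
    assemble_metacommunity,
    patristic_matrix,
    simulate_tree,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small selection-regime metacommunity shared across read-only tests."""
    cfg = SimulationConfig(
        n_taxa=40, n_ponds=3, timepoints=[10, 20, 30], replicates_per_pond=3,
        depth_mean=5_000, regime="homogeneous_selection", regime_strength=0.7,
        migration_rate=0.3, community_size=20_000, seed=11,
    )
    return assemble_metacommunity(cfg)


@pytest.fixture(scope="session")
def tree50():
    tree = simulate_tree(50, seed=1)
    labels, d = patristic_matrix(tree)
    return tree, labels, d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_counts(rng, n_taxa=12, n_samples=8, total=2_000) -> pd.DataFrame:
    """Helper: random count table with lognormal taxon profiles."""
    p = rng.lognormal(0, 1, size=(n_taxa, n_samples))
    p /= p.sum(axis=0, keepdims=True)
    cols = {f"S{j}": rng.multinomial(total, p[:, j]) for j in range(n_samples)}
    return pd.DataFrame(cols, index=[f"t{i}" for i in range(n_taxa)])
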