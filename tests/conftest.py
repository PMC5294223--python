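import numpy as np
import pytest

from tdgrn import engine, evaluation, simulate
from tdgrn.datatypes import TimeSeriesDataset


@pytest.fixture
def tiny_dataset():
    """Four genes, two series of five time points, handmade values."""
    rng = np.random.default_rng(42)
    profiles = {g: rng.uniform(0.5, 2.0, size=(2, 5)) for g in ["G1", "G2", "G3", "G10"]}
    return TimeSeriesDataset.from_profiles(profiles)


@pytest.fixture(scope="session")
def recovery_study():
    """Ten seeded 20-gene simulations run through the default pipeline.

    Shared by the parameter-recovery and threshold-separation checks so the
    pipeline only runs once per session.
    """
    runs = []
    for seed in range(1, 11):
        cfg = simulate.SimConfig(
            m=20, edge_density=0.05, n_series=10, n_timepoints=21,
            noise_sd=0.1, seed=seed,
        )
        data, gold = simulate.simulate(cfg)
        result = engine.run(data, "M2")
        report = evaluation.score_network(
            result.network, gold, frozenset(data.gene_ids)
        )
        runs.append({"config": cfg, "data": data, "gold": gold,
                     "result": result, "report": report})
    return runs
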