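import numpy as np
import pandas as pd
import pytest

from slime.io import CommunityTable, ExperimentDesign
from slime.simulate import SimConfig, simulate_dataset


def make_table(experiment_id, counts, days, sample_ids=None, asv_ids=None, nucleic="cDNA"):
    """Small helper: build a CommunityTable from a nested list of counts."""
    counts = np.asarray(counts, dtype=np.int64)
    n, m = counts.shape
    sample_ids = sample_ids or [f"{experiment_id}_s{i}" for i in range(n)]
    asv_ids = asv_ids or [f"A{j}" for j in range(m)]
    frame = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)
    return CommunityTable(
        experiment_id,
        frame,
        pd.Series(days, index=sample_ids, dtype=np.int64),
        pd.Series(nucleic, index=sample_ids),
    )


@pytest.fixture
def toy_table():
    # ASV totals 5, 1, 2: the middle one is a singleton
    return make_table(
        "toy",
        [[4, 0, 1], [1, 1, 1]],
        days=[-1, 3],
        asv_ids=["high", "single", "low"],
    )


@pytest.fixture
def toy_design():
    return ExperimentDesign("toy", (0,), (), (-1, 3))


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down generator conditions for fast structural tests."""
    return SimConfig(
        n_experiments=2,
        global_pool_size=200,
        shared_pool_size=60,
        shared_experiments=(),
        shared_pool_fraction=0.0,
        sampling_days=(-15, -1, 3, 8),
        injections=((0,), (0,)),
        refills=((), ()),
        h2_percent=(10.0, 10.0),
        depth=2_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study, shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=5))
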