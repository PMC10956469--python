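import numpy as np
import pandas as pd
import pytest

from pbtkit.config import ParentageConfig, ProgramSpec, SimulationConfig
from pbtkit.synth import observe, simulate_population


def small_sim_config(seed: int = 0, **kw) -> SimulationConfig:
    """Two small programs over five seasons: enough structure for every
    stage (iteroparity, repeats, strays, both mating rules) at test speed."""
    defaults = dict(
        seed=seed,
        years=tuple(range(2011, 2016)),
        programs=[
            ProgramSpec("CH", "cv", 60, "one_male"),
            ProgramSpec("NH", "coastal", 60, "two_males"),
        ],
        missing_rate=0.03,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return simulate_population(small_sim_config(seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    gt, samples = observe(small_truth)
    return small_truth, gt, samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline on the small two-program simulation."""
    from pbtkit.pipeline import PipelineConfig, run

    cfg = PipelineConfig(
        simulation=small_sim_config(seed=21),
        parentage=ParentageConfig(null_sim_size=5000),
        seed=21,
    )
    return run(cfg)


@pytest.fixture
def fast_parentage_config():
    return ParentageConfig(null_sim_size=5000)


def make_samples_frame(sample_ids, program="CH", year=2013, sex="F"):
    """Minimal metadata frame for hand-built genotype tables."""
    import datetime

    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "program": [program] * n,
            "spawn_date": [datetime.date(year - 1, 12, 15)] * n,
            "spawn_year": [year] * n,
            "phenotypic_sex": [sex] * n,
            "genetic_sex": [sex] * n,
            "resolved_sex": [sex] * n,
            "length_mm": [550.0] * n,
            "adipose_present": [False] * n,
        }
    )
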