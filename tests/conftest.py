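import pandas as pd
import pytest

from miconet import CohortDesign, CountTable, PipelineConfig
from miconet.synthetic import make_true_model, sample_counts


@pytest.fixture(scope="session")
def small_model():
    """Sparse 20-taxon ground truth."""
    return make_true_model(20, "erdos_renyi", edge_density=0.1, seed=11)


@pytest.fixture(scope="session")
def small_table(small_model):
    """20-sample cohort (10 + 10) at fixed 50k depth from one true model."""
    design = CohortDesign(
        n_baseline=10, n_post=10,
        depth_mean=50_000, depth_min=50_000, depth_max=50_000, seed=11,
    )
    return sample_counts(small_model, design)


@pytest.fixture(scope="session")
def fast_config():
    """Default analysis settings with a lighter StARS subsample count."""
    return PipelineConfig(seed=11, n_subsamples=20)


@pytest.fixture()
def toy_table():
    """Hand-sized table for threshold arithmetic."""
    counts = pd.DataFrame(
        [[980, 10, 10], [990, 5, 5], [1000, 0, 0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3"],
    )
    meta = pd.DataFrame(
        {"subject": ["a", "b", "c"], "timepoint": ["baseline"] * 3},
        index=counts.index,
    )
    return CountTable(counts=counts, metadata=meta)
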