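import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from srna_atlas import coverage, synthetic

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def jaccard(a, b) -> float:
    """Interval Jaccard: overlap length over union length (1-based inclusive)."""
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    union = (a.end - a.start + 1) + (b.end - b.start + 1) - inter
    return inter / union


@pytest.fixture(scope="session")
def default_experiment():
    """One seeded default synthetic experiment shared across tests."""
    truth, counts, tracks, reads = synthetic.default_experiment(seed=0)
    pooled = coverage.pool(list(tracks.values()))
    return truth, counts, tracks, reads, pooled


@pytest.fixture()
def toy_count_matrix():
    """Small deterministic count matrix with two 3-replicate conditions."""
    from srna_atlas.quantify import CountMatrix

    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(120, size=(50, 6)),
        index=[f"g{i}" for i in range(50)],
        columns=[f"s{i}" for i in range(6)],
    )
    samples = pd.DataFrame(
        {"condition": ["x"] * 3 + ["y"] * 3, "replicate": [1, 2, 3, 1, 2, 3]},
        index=counts.columns,
    )
    return CountMatrix(counts, pd.Series(80, index=counts.index), samples)
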