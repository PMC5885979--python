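import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gmprnorm.io import CountTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_table() -> CountTable:
    """The hand-checkable 4-feature, 3-sample table.

    GMPR and RLE factors are (1, 0.5, 2); column totals are (70, 30, 140).
    """
    counts = np.array(
        [
            [10, 5, 20],
            [20, 10, 40],
            [0, 15, 0],
            [40, 0, 80],
        ]
    )
    return CountTable(["f1", "f2", "f3", "f4"], ["S1", "S2", "S3"], counts)


def random_table(
    rng: np.random.Generator,
    q: int,
    n: int,
    zero_prob: float = 0.3,
    max_count: int = 50,
    ensure_common_feature: bool = True,
) -> CountTable:
    """Random sparse count table; optionally guarantees a zero-free feature."""
    counts = rng.integers(1, max_count, size=(q, n))
    counts[rng.random((q, n)) < zero_prob] = 0
    if ensure_common_feature:
        counts[0, :] = rng.integers(1, max_count, size=n)
    return CountTable(
        [f"f{k}" for k in range(q)], [f"s{i}" for i in range(n)], counts
    )
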