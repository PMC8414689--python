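import numpy as np
import pytest

from zinq import Design, TaxonTable


@pytest.fixture
def small_table() -> TaxonTable:
    counts = np.array(
        [
            [0, 3, 10, 2],
            [5, 0, 8, 1],
            [2, 2, 0, 7],
            [1, 6, 4, 0],
        ]
    )
    return TaxonTable(
        counts,
        sample_ids=["s1", "s2", "s3", "s4"],
        taxon_ids=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def binary_design() -> Design:
    rng = np.random.default_rng(7)
    n = 200
    c = (rng.uniform(size=n) < 0.5).astype(float)
    age = rng.normal(50, 5, size=n)
    return Design(c, np.column_stack([np.ones(n), age]),
                  covariate_names=["intercept", "age"])
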