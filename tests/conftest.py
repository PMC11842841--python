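import dataclasses

import numpy as np
import pytest

from stance import SpatialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_dataset(
    n=40, q=8, K=3, seed=0, normalized=True, counts_scale=20
) -> SpatialDataset:
    """Small random dataset with iid Poisson counts (no spatial signal)."""
    r = np.random.default_rng(seed)
    coords = r.uniform(0, 1, (n, 2))
    comp = r.dirichlet(np.ones(K), n)
    counts = r.poisson(counts_scale, size=(q, n)).astype(float)
    ds = SpatialDataset(counts=counts, coords=coords, composition=comp)
    if normalized:
        ds = dataclasses.replace(ds, normalized=r.normal(size=(q, n)))
    return ds


@pytest.fixture
def small_dataset():
    return make_dataset()
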