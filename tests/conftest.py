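import numpy as np
import pytest
from hypothesis import settings

from thorlink import OtuTable, SyntheticConfig, generate_dataset, metadata_by_sample, rarefy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> OtuTable:
    """3 samples x 4 OTUs with per-sample totals 10, 20, 30."""
    counts = np.array(
        [
            [1, 2, 3, 4],
            [5, 5, 5, 5],
            [10, 0, 10, 10],
        ]
    )
    return OtuTable(["S1", "S2", "S3"], ["OTU1", "OTU2", "OTU3", "OTU4"], counts)


@pytest.fixture(scope="session")
def default_dataset():
    """One study-sized synthetic bundle shared across tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def rarefied_default(default_dataset):
    rt = rarefy(default_dataset.table, depth=5000, seed=11)
    meta = metadata_by_sample(default_dataset.metadata)
    meta = {s: meta[s] for s in rt.table.sample_ids}
    return rt, meta
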