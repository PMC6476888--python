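import numpy as np
import pytest

from naphqsar import datasets, structures


@pytest.fixture(scope="session")
def records():
    return datasets.parse_activity_table()


@pytest.fixture(scope="session")
def by_id(records):
    return {r.id: r for r in records}


@pytest.fixture(scope="session")
def small_conformers(by_id):
    """Embedded, charged, template-aligned conformers of five compounds."""
    ids = ["1", "4c", "5s", "7f", "8c"]
    smiles = {cid: datasets.build_smiles(by_id[cid]) for cid in ids}
    return structures.build_aligned_series(smiles, template_id="1", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
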