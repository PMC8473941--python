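import hypothesis
import pytest

from gdgtbudget.community import CountTable, abundance_profiles
from gdgtbudget.lipid_quant import build_profiles
from gdgtbudget.synthetic import SyntheticConfig, generate

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (fixed seed)."""
    return generate(SyntheticConfig(), seed=11)


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    return build_profiles(default_dataset.peak_records())


@pytest.fixture(scope="session")
def default_taxon_profiles(default_dataset):
    ds = default_dataset
    tbl = CountTable(counts=ds.count_table, taxonomy=ds.taxonomy)
    ddpcr = dict(zip(ds.ddpcr.sample_id, ds.ddpcr.copies_per_L))
    return abundance_profiles(tbl, ddpcr)
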