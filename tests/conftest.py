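import logging

import pytest

from skimbarcode.seqio import RegionAlignment, build_datasets
from skimbarcode.simulate import default_config, simulate_dataset

logging.getLogger("skimbarcode").setLevel(logging.ERROR)


def make_alignment(sequences, samples=None, name="region", compartment="plastid_gene"):
    samples = samples or [f"s{i+1}" for i in range(len(sequences))]
    return RegionAlignment(
        region_name=name, compartment=compartment, samples=samples, sequences=list(sequences)
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default study design, simulated once per session."""
    return simulate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def default_datasets(default_dataset):
    return build_datasets(default_dataset.regions)


@pytest.fixture()
def aln_factory():
    return make_alignment
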