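import pytest

from venomkit.seqio import load_table2, load_table3
from venomkit.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table2_by_name(table2):
    return {r.name: r for r in table2}


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Seeded noiseless synthetic venom-gland set (200 precursors)."""
    return generate_dataset(
        GeneratorConfig(seed=11, mass_noise_sd=0.0, dropout=0.0, n_decoys=10)
    )
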