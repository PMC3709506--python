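import pytest

from catpase_ms.synthetic_data import (
    GroundTruth,
    InstrumentModel,
    gen_protein_sequences,
    gen_xl_run,
)


@pytest.fixture(scope="session")
def small_sequences():
    """Three short proteins with lysines every 12 residues."""
    return gen_protein_sequences(["alpha", "beta", "gamma"], length=80, seed=1)


@pytest.fixture(scope="session")
def xl_truth():
    return GroundTruth(
        links=[
            ("alpha", 12, "beta", 24, 1.0),
            ("beta", 36, "gamma", 48, 1.0),
            ("alpha", 36, "gamma", 12, 1.0),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def xl_run(small_sequences, xl_truth):
    """Noise-free identification run with two injected decoys."""
    return gen_xl_run(small_sequences, xl_truth, n_decoys=2)


@pytest.fixture(scope="session")
def native_model():
    return InstrumentModel(resolution=1000, charge_range=(35, 55))
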