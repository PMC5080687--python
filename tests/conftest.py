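import numpy as np
import pytest
from hypothesis import settings

from ibferm import EndpointRecord, fixtures

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fx():
    return fixtures()


def random_record(rng: np.random.Generator, label: str = "random") -> EndpointRecord:
    """A random but valid glucose/glycerol endpoint for oracle comparisons."""
    return EndpointRecord(
        label=label,
        duration_h=float(rng.uniform(8, 48)),
        substrates_consumed={
            "glucose": float(rng.uniform(0.5, 50)),
            "glycerol": float(rng.uniform(0, 20)),
        },
        products={
            "butanol": float(rng.uniform(0, 10)),
            "isopropanol": float(rng.uniform(0, 5)),
            "acetone": float(rng.uniform(0, 1)),
            "acetic_acid": float(rng.uniform(0, 2)),
            "butyric_acid": float(rng.uniform(0, 5)),
        },
    )
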