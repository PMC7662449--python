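import numpy as np
import pytest

from gbckit import AlleleFrequencyTable, make_scenarios


@pytest.fixture(scope="session")
def scenarios():
    """Named composite-breed fixtures shared across the suite."""
    return make_scenarios(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20201030)


def random_freq_table(rng, M: int, K: int) -> AlleleFrequencyTable:
    freq = rng.uniform(0.05, 0.95, size=(M, K))
    return AlleleFrequencyTable(
        [f"snp{i}" for i in range(M)], [f"breed{k}" for k in range(K)], freq
    )
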