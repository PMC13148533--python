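import numpy as np
import pytest

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
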