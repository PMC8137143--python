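import random

import numpy as np
import pytest

from adscreen.seq_features import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_peptides():
    r = random.Random(7)

    def make(n: int, length: int) -> list[str]:
        return ["".join(r.choices(AMINO_ACIDS, k=length)) for _ in range(n)]

    return make
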