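import numpy as np
import pytest

import mappability as mp


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_collection():
    """Single genome 'ACGTACGT' with its index."""
    col = mp.collection_from_strings(["ACGTACGT"])
    return col, mp.build_index(col)


def random_dna(rng, n, skew=False):
    p = [0.4, 0.1, 0.1, 0.4] if skew else None
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
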