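import numpy as np
import pytest

from gh45tools import resdiag
from gh45tools.seqmodel import PROTEIN_ALPHABET


@pytest.fixture(scope="session")
def scheme():
    return resdiag.default_scheme()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(PROTEIN_ALPHABET), size=length))
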