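import numpy as np
import pytest

from siliscan.align import load_reference


@pytest.fixture(scope="session")
def profile():
    return load_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20201612)


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, length, alphabet=AA):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
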