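import numpy as np
import pytest

from softshape.geometry import reference_set


@pytest.fixture(scope="session")
def refs():
    """The five canonical reference shapes (97 px on a 512 canvas)."""
    return reference_set()


@pytest.fixture(scope="session")
def refs_by_name(refs):
    return {r.name: r for r in refs}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
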