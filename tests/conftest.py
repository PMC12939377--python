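import numpy as np
import pytest

from hrvlit import MLRD
from hrvlit.fixtures import REFERENCE_EVIDENCE_COUNTS


@pytest.fixture(scope="session")
def reference_mlrd() -> MLRD:
    """The bundled reference directional counts as an MLRD (no provenance)."""
    return MLRD(counts=dict(REFERENCE_EVIDENCE_COUNTS))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
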