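import numpy as np
import pytest
from hypothesis import settings

from grlscreen.io import ProteinRecord

# property tests must be reproducible run-to-run
settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_records():
    return [
        ProteinRecord(id="a", sequence="MKVLIVFADE"),
        ProteinRecord(id="b", sequence="MKVLIVFADE"),
        ProteinRecord(id="c", sequence="ACDEFGHIKL"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20201204)
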