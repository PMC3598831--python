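import numpy as np
import pytest
from hypothesis import settings

import thintail as tt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def uniform() -> tt.CompositionModel:
    return tt.CompositionModel.uniform()


@pytest.fixture
def example_record() -> tt.SequenceRecord:
    """The 12-mer used throughout as the worked example."""
    return tt.SequenceRecord(id="example", seq="ACGACGCCGACT")


@pytest.fixture
def random_record() -> tt.SequenceRecord:
    rng = np.random.default_rng(1234)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    return tt.SequenceRecord(id="rand800", seq=seq)
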