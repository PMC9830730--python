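import numpy as np
import pytest

from emboliseq.models import CASE_GROUP, CTRL_GROUP, CountMatrix, SampleDesign
from emboliseq.simulate import SimulationConfig


@pytest.fixture
def design() -> SampleDesign:
    """The 6-vs-5 two-group layout used throughout."""
    return SimulationConfig(seed=0).design()


@pytest.fixture
def small_design() -> SampleDesign:
    return SampleDesign(
        ["a1", "a2", "b1", "b2"],
        [CASE_GROUP, CASE_GROUP, CTRL_GROUP, CTRL_GROUP],
    )


@pytest.fixture
def toy_counts(design) -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(100, size=(50, len(design.sample_ids)))
    return CountMatrix([f"g{i}" for i in range(50)], design, counts)
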