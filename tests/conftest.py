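from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cilipop.codons import get_code
from cilipop.diversity import HaplotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code1():
    return get_code(1)


@pytest.fixture(scope="session")
def code6():
    return get_code(6)


@pytest.fixture
def worked_matrix() -> HaplotypeMatrix:
    """The 4-haplotype, 3-site matrix {000, 100, 110, 111} used as the
    hand-checked anchor for S, k-hat and Tajima's D."""
    rows = np.array([
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [1, 1, 1],
    ], dtype=np.int8)
    return HaplotypeMatrix(rows, [("c", 10), ("c", 20), ("c", 30)], 3)
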