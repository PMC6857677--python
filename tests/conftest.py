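import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laketsi import LakeSample, TrophicState

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def published_confusion_matrix():
    """Consensus hold-out confusion matrix from the published national-survey
    fit (rows actual, columns predicted; 73 lakes)."""
    return np.array(
        [
            [7, 1, 0, 0],
            [1, 14, 9, 2],
            [0, 0, 16, 8],
            [0, 1, 4, 10],
        ]
    )


@pytest.fixture
def small_lakes():
    """Six hand-written lakes spanning the trophic gradient."""
    return [
        LakeSample("clear-1", 8.0, 200.0, 5.0, 2400.0, TrophicState.OLIGOTROPHIC),
        LakeSample("clear-2", 5.5, 300.0, 8.0, 1800.0, TrophicState.OLIGOTROPHIC),
        LakeSample("mid-1", 2.5, 600.0, 20.0, 500.0, TrophicState.MESOTROPHIC),
        LakeSample("mid-2", 1.8, 800.0, 35.0, 350.0, TrophicState.EUTROPHIC),
        LakeSample("green-1", 0.6, 1800.0, 90.0, 120.0, TrophicState.EUTROPHIC),
        LakeSample("green-2", 0.3, 3200.0, 250.0, 60.0, TrophicState.HYPEREUTROPHIC),
    ]
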