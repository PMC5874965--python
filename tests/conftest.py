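import numpy as np
import pytest

from tomospc import (
    ExperimentSpec,
    SeriesSpec,
    generate_experiment,
    generate_series,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20170721)


@pytest.fixture
def in_control_series():
    """A clean 90-observation window at a typical operating point."""
    series, _ = generate_series(SeriesSpec(n=90, mean_mm=0.0, sd_mm=0.3, seed=11))
    return series


@pytest.fixture
def default_experiment():
    trials, truth = generate_experiment(ExperimentSpec(seed=7))
    return trials, truth
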