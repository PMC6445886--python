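import numpy as np
import pytest

from benchmeta.datatypes import EffectSize, StudyRecord


@pytest.fixture
def three_effects():
    """Hand-checkable heterogeneous set: theta = {0, 1, 2}, se = 0.5.

    Fixed-effect weights are 4 each, theta_FE = 1, Q = 8, c = 8.
    """
    return [EffectSize(f"s{i}", float(t), 0.5, 5) for i, t in enumerate((0, 1, 2))]


@pytest.fixture
def homogeneous_effects():
    return [EffectSize(f"s{i}", 1.0, 0.5, 5) for i in range(3)]


@pytest.fixture
def outlier_effects():
    """Three consistent studies plus one strong outlier (tight ses)."""
    return [EffectSize(f"s{i}", float(t), 0.1, 5)
            for i, t in enumerate((0.0, 0.0, 0.0, 5.0))]


@pytest.fixture
def record_with_control():
    return StudyRecord("rc", mean_treatment=2.0, sd_treatment=1.0, n_treatment=10,
                       mean_control=0.0, sd_control=1.0, n_control=10)
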