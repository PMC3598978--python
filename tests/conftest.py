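import numpy as np
import pytest

from cardiocirc import (ARModel, DEFAULT_COEFFICIENTS, CircadianCoefficients,
                        SubjectProfile)


@pytest.fixture
def female_30():
    return SubjectProfile("f30", sex=0, age=30.0)


@pytest.fixture
def male_30():
    return SubjectProfile("m30", sex=1, age=30.0)


@pytest.fixture
def noiseless_coeffs():
    """Reference coefficients with sigma = 0 (deterministic model)."""
    return CircadianCoefficients(**{**DEFAULT_COEFFICIENTS.to_dict(), "sigma": 0.0})


@pytest.fixture
def white_noise_ar():
    """Pure white-noise residual process with SD equal to the model sigma."""
    return ARModel(alphas=(), tau=0.15)


@pytest.fixture
def silent_ar():
    return ARModel(alphas=(), tau=0.0)


@pytest.fixture
def mixed_cohort():
    """Six subjects spanning both sexes and a range of ages."""
    return [
        SubjectProfile("a", 0, 22.0), SubjectProfile("b", 0, 34.0),
        SubjectProfile("c", 0, 47.0), SubjectProfile("d", 1, 27.0),
        SubjectProfile("e", 1, 36.0), SubjectProfile("f", 1, 44.0),
    ]


@pytest.fixture
def hour_grid():
    return np.linspace(0.0, 24.0, 97)[:-1]  # 15-min grid over one day
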