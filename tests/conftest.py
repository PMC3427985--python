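import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plantpts1.alphabet import AMINO_ACIDS, POSITIONS
from plantpts1.pwm import PWM, uniform_background

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_random_pwm(rng: np.random.Generator, scale: float = 0.15) -> PWM:
    scores = pd.DataFrame(
        rng.normal(0.0, scale, size=(14, 20)),
        index=list(POSITIONS),
        columns=list(AMINO_ACIDS),
    )
    return PWM(scores=scores, background=uniform_background(), n_positive=100)


def make_random_window(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=14))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_pwm(rng) -> PWM:
    return make_random_pwm(rng)
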