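import numpy as np
import pytest

from gaitmill import GaitSchedule, gen_gait


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_gait():
    """Square-wave FSR fixture: 10 cycles of 2 s, first heel-strike at 1 s.

    Stance is 0.9 s per cycle, so heel-strikes fall at 1, 3, 5, ... s and
    toe-offs at 1.9, 3.9, ... s; swing is the remaining 1.1 s.
    """
    schedule = GaitSchedule(
        cycle_duration=2.0, stance_fraction=0.45, n_cycles=10, jitter_sd=0.0, start=1.0
    )
    heel, toe, truth = gen_gait(schedule, fs=1000.0, seed=0)
    return heel, toe, truth
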