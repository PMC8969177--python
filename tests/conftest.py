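import numpy as np
import pytest

from meapipe import (
    PlateScenario,
    SpikeTrain,
    TrainModel,
    default_template,
)

FS = 12_500.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def template():
    return default_template(FS)


@pytest.fixture
def small_scenario():
    """One 48-well-plate well, 16 electrodes, 20 s: fast to synthesize."""
    return PlateScenario(
        plate_type=48,
        duration_s=20.0,
        wells={"A1": TrainModel(mode="bursting", tonic_rate_hz=0.5, seed=0)},
        amplitude_range_v=(30e-6, 60e-6),
    )


def make_train(times, duration=60.0, **kw):
    return SpikeTrain(np.asarray(times, dtype=float), duration, **kw)
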