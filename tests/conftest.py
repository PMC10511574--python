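import numpy as np
import pytest

from refluxsap import PHTrace, SymptomEventLog


def make_trace(ph_values, dt=6.0, recording_id="t", posture=None, meals=None,
               duration_s=None):
    """Build a regularly sampled trace from a pH value sequence."""
    ph = np.asarray(ph_values, dtype=float)
    times = np.arange(len(ph)) * dt
    return PHTrace(
        recording_id=recording_id,
        times=times,
        ph=ph,
        sample_interval_s=dt,
        duration_s=duration_s,
        posture_intervals=posture,
        meal_intervals=list(meals or []),
    )


@pytest.fixture
def flat_trace():
    """Ten minutes of flat pH 6.8 at 6-s sampling (100 samples)."""
    return make_trace([6.8] * 100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_log():
    return SymptomEventLog(
        recording_id="t",
        tracked_symptoms=("heartburn", "cough"),
        events=[(10.0, "heartburn"), (250.0, "cough"), (260.0, "heartburn")],
    )
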