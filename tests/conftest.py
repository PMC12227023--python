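import numpy as np
import pytest
from hypothesis import settings

from accomstep import SimConfig, simulate_cohort
from accomstep.preprocess import MovementTrace, compute_velocity
from accomstep.recordings import RecordingFile, StimulusEvent
from accomstep.synth import ResponseParams, simulate_movement

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_trace(refraction, fs=50.0, direction="focus", **kw):
    """MovementTrace from a raw aligned refraction vector (no filtering)."""
    refraction = np.asarray(refraction, dtype=float)
    return MovementTrace(
        participant_id=kw.pop("participant_id", "P01"),
        cue=kw.pop("cue", "BDP"),
        direction=direction,
        t=np.arange(refraction.size) / fs,
        refraction=refraction,
        velocity=compute_velocity(refraction, fs),
        fs=fs,
        **kw,
    )


def make_recording(od, os_=None, fs=50.0, events=None, participant_id="P01", cue="BDP"):
    od = np.asarray(od, dtype=float)
    os_ = od.copy() if os_ is None else np.asarray(os_, dtype=float)
    return RecordingFile(
        participant_id=participant_id, cue=cue, fs=fs,
        time=np.arange(od.size) / fs, od=od, os=os_,
        events=events or [],
    )


def single_movement_recording(params: ResponseParams, fs=50.0, duration=5.0):
    """One-movement recording whose event log segments the full window."""
    t, x = simulate_movement(params, fs, duration, seed=0)
    ev = StimulusEvent(0, params.direction, 0.0,
                       *( (1.0, 2.5) if params.direction == "focus" else (2.5, 1.0) ))
    return make_recording(x, x.copy(), fs=fs, events=[ev])


@pytest.fixture(scope="session")
def small_cohort():
    """4-participant cohort with the default study conditions."""
    return simulate_cohort(SimConfig(n_participants=4, seed=777))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise- and artifact-free cohort: closed forms hold exactly."""
    return simulate_cohort(SimConfig(
        n_participants=3, seed=777, noise_sd=0.0, gap_rate=0.0,
        participant_sd=0.0, movement_sd=0.0,
    ))
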