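import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lgnsnr.snr import Trial, TrialSet
from lgnsnr.stimuli import ColorDirection, StimulusSpec, TCSFModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tcsf() -> TCSFModel:
    return TCSFModel()


@pytest.fixture(scope="session")
def blank_spec() -> StimulusSpec:
    return StimulusSpec(color_direction=ColorDirection.BLANK, duration=1.0, ramp=0.166)


def poisson_spike_trains(
    rate: np.ndarray, dt: float, n_trials: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independent binned inhomogeneous-Poisson trains (test-side generator,
    written separately from the package's sampler so oracle comparisons stay
    independent of the code path under test)."""
    counts = rng.poisson(rate * dt, size=(n_trials, len(rate)))
    starts = np.arange(len(rate)) * dt
    out = []
    for c in counts:
        idx = np.repeat(np.arange(len(rate)), c)
        out.append(np.sort(starts[idx] + rng.random(len(idx)) * dt))
    return out


def make_trial_set(
    stim_trains: list[np.ndarray],
    blank_trains: list[np.ndarray],
    frequency_hz: float,
    duration: float = 1.0,
    contrast: float = 0.05,
) -> TrialSet:
    """Assemble a two-condition TrialSet from raw spike-time arrays."""
    spec = StimulusSpec(
        color_direction=ColorDirection.L_PLUS_M,
        temporal_frequency=frequency_hz,
        cone_contrast=contrast,
        duration=duration,
        ramp=0.0,
    )
    blank = StimulusSpec(
        color_direction=ColorDirection.BLANK, duration=duration, ramp=0.0
    )
    trials = [
        Trial(trial_id=i, condition_id="stim", spike_times=st)
        for i, st in enumerate(stim_trains)
    ] + [
        Trial(trial_id=len(stim_trains) + i, condition_id="blank", spike_times=st)
        for i, st in enumerate(blank_trains)
    ]
    return TrialSet(
        trials=trials,
        conditions={"stim": spec, "blank": blank},
        stim_on=0.0,
        stim_off=duration,
    )
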