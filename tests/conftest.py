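"""Shared fixtures: simulated recordings and constructed waveforms."""

from __future__ import annotations

import numpy as np
import pytest

from hippophys.sweeps import StepStimulus, Sweep
from hippophys.synthgen import (
    StimulusProtocol,
    get_preset,
    simulate_current_clamp,
)

FULL_AMPLITUDES = tuple(np.arange(25.0, 450.1, 25.0))


@pytest.fixture(scope="session")
def full_protocol() -> StimulusProtocol:
    """Hyperpolarizing pair plus a 25-450 pA depolarizing family at 20 kHz."""
    return StimulusProtocol(
        step_amplitudes=(-50.0, -25.0) + FULL_AMPLITUDES,
        pre_step_duration=100.0,
        step_duration=750.0,
        post_step_duration=50.0,
        sampling_rate=20.0,
    )


@pytest.fixture(scope="session")
def nmr_recording(full_protocol):
    return simulate_current_clamp(get_preset("naked_mole_rat"), full_protocol, seed=1)


@pytest.fixture(scope="session")
def mouse_recording(full_protocol):
    return simulate_current_clamp(get_preset("mouse"), full_protocol, seed=1)


def gaussian_bump_sweep(
    peak_times_ms,
    peak_mv: float = 20.0,
    baseline_mv: float = -70.0,
    width_ms: float = 1.0,
    duration_ms: float = 1000.0,
    sampling_rate: float = 20.0,
    stimulus: StepStimulus | None = None,
) -> Sweep:
    """A current-clamp sweep made of Gaussian 'spikes' at known times."""
    t = np.arange(0.0, duration_ms, 1.0 / sampling_rate)
    v = np.full_like(t, baseline_mv)
    for pt in np.atleast_1d(peak_times_ms):
        v += (peak_mv - baseline_mv) * np.exp(-0.5 * ((t - pt) / width_ms) ** 2)
    return Sweep(samples=v, sampling_rate=sampling_rate, clamp_mode="current",
                 stimulus=stimulus)
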