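"""Synthetic voltage-clamp traces with Poisson-timed synaptic currents.

The simulated current is a flat baseline plus a superposition of
biexponential PSC kernels at Poisson event times, with log-normal
amplitudes, plus white Gaussian recording noise.  Event amplitude sign
follows the driving force of each transmitter class: amplitude is
proportional to (holding - reversal), so glutamatergic events are
inward (negative) below 0 mV and GABAergic events are outward above
E_Cl.  Ground truth lists every injected event with its class, time and
signed amplitude, so downstream detector performance can be scored
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError
from ..sweeps import Sweep
from ..vclamp_events import EXC_KERNEL, INH_KERNEL, PSCKernel
from .model import SimulatedRecording

__all__ = ["SynapticParams", "simulate_voltage_clamp"]

REFERENCE_DRIVING_FORCE = 60.0  # mV; amplitude scale is defined at this driving force


@dataclass(frozen=True)
class SynapticParams:
    """Kernel shapes, amplitude statistics and reversals for both classes."""

    exc_kernel: PSCKernel = EXC_KERNEL
    inh_kernel: PSCKernel = INH_KERNEL
    exc_reversal: float = 0.0  # mV, mixed-cation convention
    inh_reversal: float = -65.6  # mV, chloride Nernst potential of the recipes
    amp_median: float = 20.0  # pA at the reference driving force
    amp_sigma: float = 0.4  # log-normal shape parameter
    noise_sd: float = 2.0  # pA, white recording noise
    baseline: float = 0.0  # pA


def simulate_voltage_clamp(
    holding_potential: float,
    exc_rate: float,
    inh_rate: float,
    duration: float,
    seed: int,
    sampling_rate: float = 20.0,
    params: SynapticParams = SynapticParams(),
) -> SimulatedRecording:
    """Simulate one voltage-clamp sweep.

    Parameters
    ----------
    holding_potential:
        Command potential in mV; sets the sign and scale of each class's
        events through its driving force.
    exc_rate, inh_rate:
        Poisson rates in Hz for glutamatergic and GABAergic events.
    duration:
        Sweep duration in seconds.
    sampling_rate:
        kHz.
    """
    if exc_rate < 0 or inh_rate < 0:
        raise ConfigError("event rates must be >= 0")
    if duration <= 0:
        raise ConfigError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * 1000.0 * sampling_rate))
    trace = np.full(n, params.baseline, dtype=float)

    times_all, amps_all, classes_all = [], [], []
    for cls, rate, kernel, rev in (
        ("exc", exc_rate, params.exc_kernel, params.exc_reversal),
        ("inh", inh_rate, params.inh_kernel, params.inh_reversal),
    ):
        count = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration * 1000.0, size=count))  # ms
        driving = holding_potential - rev
        if count and driving == 0.0:
            warnings.warn(
                f"holding equals the {cls} reversal ({rev} mV): "
                "zero-amplitude events for that class"
            )
        mags = rng.lognormal(np.log(params.amp_median), params.amp_sigma, size=count)
        amps = mags * driving / REFERENCE_DRIVING_FORCE
        impulses = np.zeros(n)
        idx = np.minimum((times * sampling_rate).astype(int), n - 1)
        np.add.at(impulses, idx, amps)
        if count:
            trace += np.convolve(impulses, kernel.waveform(sampling_rate))[:n]
        times_all.append(times)
        amps_all.append(amps)
        classes_all.append(np.full(count, cls))

    if params.noise_sd > 0:
        trace += rng.normal(0.0, params.noise_sd, size=n)

    order = np.argsort(np.concatenate(times_all), kind="stable")
    sweep = Sweep(
        samples=trace,
        sampling_rate=sampling_rate,
        clamp_mode="voltage",
        holding_potential=holding_potential,
    )
    return SimulatedRecording(
        sweeps=[sweep],
        event_times=np.concatenate(times_all)[order],
        event_amplitudes=np.concatenate(amps_all)[order],
        event_classes=np.concatenate(classes_all)[order],
        seed=seed,
    )
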