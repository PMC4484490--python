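"""Single-compartment conductance-based neuron model and current-clamp simulation.

The membrane carries a leak, transient-sodium and delayed-rectifier
potassium spiking currents with Traub-Miles-style kinetics, and one slow
voltage-gated potassium (M-type) conductance that produces spike-frequency
adaptation and the afterhyperpolarization.  This is the smallest model that
reproduces the qualitative repertoire the feature extractor is tested
against: overshooting action potentials, AHPs, adaptation, and a stable
rheobase under a family of rectangular current steps.

All quantities use the package-wide unit convention: mV, ms, pA, nS, pF.
The membrane equation is

    C dV/dt = I_inj - gL (V - EL) - gNa m^3 h (V - ENa)
              - gK n^4 (V - EK) - gM z (V - EK) + noise

integrated with a fixed internal sub-step (default 0.01 ms, never coarser
than 0.01 ms) and exponential-Euler gate updates; the trace is decimated
to the protocol sampling rate.  Membrane noise is an Ornstein-Uhlenbeck
voltage perturbation whose stationary standard deviation equals the
preset's ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..errors import ConfigError, IntegrationError
from ..sweeps import StepStimulus, Sweep

__all__ = [
    "NeuronPreset",
    "StimulusProtocol",
    "SimulatedRecording",
    "simulate_current_clamp",
]

MAX_SUBSTEP_MS = 0.01  # internal integration sub-step ceiling (10 µs)


@dataclass(frozen=True)
class NeuronPreset:
    """Immutable parameter set for the single-compartment model.

    ``spike_channel_params`` holds the maximal conductances and kinetic
    constants of the spiking currents:

    - ``gna`` / ``ena``: transient Na+ maximal conductance (nS) and reversal (mV)
    - ``gk`` / ``ek``: delayed-rectifier K+ maximal conductance (nS) and reversal (mV)
    - ``vt``: spike-kinetics voltage shift (mV); more negative lowers threshold
    - ``adaptation_tau_max``: peak time constant of the adaptation gate (ms)
    """

    name: str
    membrane_capacitance: float  # pF
    leak_conductance: float  # nS
    leak_reversal: float  # mV
    spike_channel_params: Mapping[str, float]
    adaptation_strength: float  # nS, M-type conductance
    noise_sd: float  # mV, stationary SD of membrane noise

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0:
            raise ConfigError("membrane_capacitance must be > 0")
        if self.leak_conductance < 0 or self.adaptation_strength < 0:
            raise ConfigError("conductances must be >= 0")
        for key in ("gna", "gk"):
            if self.spike_channel_params.get(key, 0.0) < 0:
                raise ConfigError(f"spike conductance {key!r} must be >= 0")
        object.__setattr__(
            self, "spike_channel_params", dict(self.spike_channel_params)
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """A family of rectangular current steps sharing one timing layout."""

    step_amplitudes: tuple[float, ...]
    pre_step_duration: float = 100.0  # ms
    step_duration: float = 750.0  # ms
    post_step_duration: float = 150.0  # ms
    sampling_rate: float = 20.0  # kHz

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_amplitudes", tuple(self.step_amplitudes))
        for dur in (self.pre_step_duration, self.step_duration, self.post_step_duration):
            if dur <= 0:
                raise ConfigError("protocol durations must be positive")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")

    @property
    def total_duration(self) -> float:
        return self.pre_step_duration + self.step_duration + self.post_step_duration

    def stimulus(self, amplitude: float) -> StepStimulus:
        return StepStimulus(self.pre_step_duration, self.step_duration, amplitude)


@dataclass
class SimulatedRecording:
    """Sweeps plus the generator's ground truth, keyed by sweep index."""

    sweeps: list[Sweep]
    spike_times: list[np.ndarray] = field(default_factory=list)  # ms, per sweep
    spike_peaks: list[np.ndarray] = field(default_factory=list)  # mV, per sweep
    event_times: np.ndarray | None = None  # voltage clamp, ms
    event_amplitudes: np.ndarray | None = None  # pA, signed
    event_classes: np.ndarray | None = None  # "exc" / "inh"
    seed: int | None = None


def _vtrap(x: np.ndarray) -> np.ndarray:
    """x / (exp(x) - 1) with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / np.expm1(safe)
    return np.where(small, 1.0 - x / 2.0, out)


def _gate_rates(v: np.ndarray, vt: float):
    """Traub-Miles rate constants (1/ms) for m, h, n at voltage v."""
    u = v - vt
    am = 1.28 * _vtrap((13.0 - u) / 4.0)
    bm = 1.4 * _vtrap((u - 40.0) / 5.0)
    ah = 0.128 * np.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    an = 0.16 * _vtrap((15.0 - u) / 5.0)
    bn = 0.5 * np.exp((10.0 - u) / 40.0)
    return am, bm, ah, bh, an, bn


def _adaptation_kinetics(v: np.ndarray, tau_max: float):
    """M-type gate: steady state and voltage-dependent time constant (ms)."""
    zinf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tz = tau_max / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    return zinf, np.maximum(tz, 1.0)


def _ground_truth_spikes(v: np.ndarray, dt: float, cut: float = 0.0):
    """Local maxima above ``cut`` mV on the output-sampled trace."""
    if v.size < 3:
        return np.array([]), np.array([])
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > cut)
    idx = np.flatnonzero(interior) + 1
    # collapse plateau duplicates closer than 1 ms (cannot be distinct APs)
    if idx.size > 1:
        keep = np.concatenate(([True], np.diff(idx) * dt > 1.0))
        idx = idx[keep]
    return idx * dt, v[idx]


def _integrate_numpy(amps, state, params, h, n_out, n_sub, k_on, k_off, kicks, traces):
    """Reference integrator, vectorized over sweeps.  Returns the index of
    the first sweep whose state went non-finite, or -1 on success."""
    cm, gl, el, gna, ena, gk, ek, gm, vt, tau_max, noise_decay = params
    v, m, hh, n, z, eta = state
    have_noise = kicks.shape[0] > 0
    k = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for i_out in range(n_out):
            for _ in range(n_sub):
                i_inj = amps if k_on <= k < k_off else 0.0
                vm = v + eta
                am, bm, ah, bh, an, bn = _gate_rates(vm, vt)
                zinf, tz = _adaptation_kinetics(vm, tau_max)
                i_ion = (
                    gl * (vm - el)
                    + gna * m**3 * hh * (vm - ena)
                    + gk * n**4 * (vm - ek)
                    + gm * z * (vm - ek)
                )
                v = v + h * (i_inj - i_ion) / cm
                tau = 1.0 / (am + bm)
                inf = am * tau
                m = inf + (m - inf) * np.exp(-h / tau)
                tau = 1.0 / (ah + bh)
                inf = ah * tau
                hh = inf + (hh - inf) * np.exp(-h / tau)
                tau = 1.0 / (an + bn)
                inf = an * tau
                n = inf + (n - inf) * np.exp(-h / tau)
                z = zinf + (z - zinf) * np.exp(-h / tz)
                if have_noise:
                    eta = eta * noise_decay + kicks[k]
                k += 1
            if not np.all(np.isfinite(v)):
                return int(np.flatnonzero(~np.isfinite(v))[0])
            traces[i_out] = v + eta
    return -1


try:  # compiled fast path; the numpy loop above is the fallback
    import math

    from numba import njit

    @njit(cache=False)
    def _integrate_numba(amps, state, params, h, n_out, n_sub, k_on, k_off, kicks, traces):
        cm, gl, el = params[0], params[1], params[2]
        gna, ena, gk, ek, gm = params[3], params[4], params[5], params[6], params[7]
        vt, tau_max, noise_decay = params[8], params[9], params[10]
        have_noise = kicks.shape[0] > 0
        for j in range(amps.shape[0]):
            v, m, hh, n = state[0, j], state[1, j], state[2, j], state[3, j]
            z, eta = state[4, j], state[5, j]
            k = 0
            for i_out in range(n_out):
                for _ in range(n_sub):
                    i_inj = amps[j] if k_on <= k < k_off else 0.0
                    vm = v + eta
                    u = vm - vt
                    x = (13.0 - u) / 4.0
                    am = 1.28 * (1.0 - x / 2.0 if abs(x) < 1e-7 else x / math.expm1(x))
                    x = (u - 40.0) / 5.0
                    bm = 1.4 * (1.0 - x / 2.0 if abs(x) < 1e-7 else x / math.expm1(x))
                    ah = 0.128 * math.exp((17.0 - u) / 18.0)
                    bh = 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
                    x = (15.0 - u) / 5.0
                    an = 0.16 * (1.0 - x / 2.0 if abs(x) < 1e-7 else x / math.expm1(x))
                    bn = 0.5 * math.exp((10.0 - u) / 40.0)
                    zinf = 1.0 / (1.0 + math.exp(-(vm + 35.0) / 10.0))
                    tz = tau_max / (
                        3.3 * math.exp((vm + 35.0) / 20.0) + math.exp(-(vm + 35.0) / 20.0)
                    )
                    if tz < 1.0:
                        tz = 1.0
                    i_ion = (
                        gl * (vm - el)
                        + gna * m * m * m * hh * (vm - ena)
                        + gk * n * n * n * n * (vm - ek)
                        + gm * z * (vm - ek)
                    )
                    v = v + h * (i_inj - i_ion) / cm
                    tau = 1.0 / (am + bm)
                    inf = am * tau
                    m = inf + (m - inf) * math.exp(-h / tau)
                    tau = 1.0 / (ah + bh)
                    inf = ah * tau
                    hh = inf + (hh - inf) * math.exp(-h / tau)
                    tau = 1.0 / (an + bn)
                    inf = an * tau
                    n = inf + (n - inf) * math.exp(-h / tau)
                    z = zinf + (z - zinf) * math.exp(-h / tz)
                    if have_noise:
                        eta = eta * noise_decay + kicks[k, j]
                    k += 1
                if not math.isfinite(v):
                    return j
                traces[i_out, j] = v + eta
        return -1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def simulate_current_clamp(
    preset: NeuronPreset,
    protocol: StimulusProtocol,
    seed: int,
    v0: float | None = None,
) -> SimulatedRecording:
    """Integrate the membrane equation once per step amplitude.

    All amplitudes in the protocol are integrated in lockstep (the state
    is vectorized over sweeps), so a full rheobase family costs a single
    pass.  Deterministic for a fixed ``(preset, protocol, seed)``.
    """
    rng = np.random.default_rng(seed)
    p = preset.spike_channel_params
    gna, ena = p["gna"], p["ena"]
    gk, ek = p["gk"], p["ek"]
    vt = p.get("vt", -60.0)
    tau_max = p.get("adaptation_tau_max", 600.0)
    cm = preset.membrane_capacitance
    gl, el = preset.leak_conductance, preset.leak_reversal
    gm = preset.adaptation_strength

    dt_out = 1.0 / protocol.sampling_rate
    n_sub = max(1, int(np.ceil(dt_out / MAX_SUBSTEP_MS)))
    h = dt_out / n_sub
    n_out = int(round(protocol.total_duration / dt_out))
    amps = np.asarray(protocol.step_amplitudes, dtype=float)
    n_sweeps = amps.size

    v = np.full(n_sweeps, el if v0 is None else v0, dtype=float)
    am, bm, ah, bh, an, bn = _gate_rates(v, vt)
    m = am / (am + bm)
    hh = ah / (ah + bh)
    n = an / (an + bn)
    z, _ = _adaptation_kinetics(v, tau_max)
    eta = np.zeros(n_sweeps)  # OU noise voltage, mV

    # OU noise: tau = membrane time constant at rest, stationary SD = noise_sd
    tau_noise = cm / max(gl, 1e-9)
    noise_decay = np.exp(-h / tau_noise)
    kick_sd = preset.noise_sd * np.sqrt(1.0 - noise_decay**2)

    on = protocol.pre_step_duration
    off = on + protocol.step_duration
    k_on = int(round(on / h))
    k_off = int(round(off / h))
    kicks = (
        rng.standard_normal((n_out * n_sub, n_sweeps)) * kick_sd
        if preset.noise_sd > 0
        else np.zeros((0, n_sweeps))
    )
    state = np.stack([v, m, hh, n, z, eta])
    params = np.array(
        [cm, gl, el, gna, ena, gk, ek, gm, vt, tau_max, noise_decay], dtype=float
    )
    traces = np.empty((n_out, n_sweeps))
    integrate = _integrate_numba if _HAVE_NUMBA else _integrate_numpy
    bad = integrate(amps, state, params, h, n_out, n_sub, k_on, k_off, kicks, traces)
    if bad >= 0:
        raise IntegrationError(
            f"non-finite membrane state during integration (step {amps[bad]:g} pA)"
        )

    rec = SimulatedRecording(sweeps=[], seed=seed)
    for j, amp in enumerate(amps):
        sw = Sweep(
            samples=traces[:, j],
            sampling_rate=protocol.sampling_rate,
            clamp_mode="current",
            stimulus=protocol.stimulus(amp),
        )
        rec.sweeps.append(sw)
        st, pk = _ground_truth_spikes(traces[:, j], dt_out)
        rec.spike_times.append(st)
        rec.spike_peaks.append(pk)
    return rec
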