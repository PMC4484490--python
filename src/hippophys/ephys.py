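"""Current-clamp feature extraction.

Implements the standard whole-cell patch-clamp feature definitions used
in the group comparison:

- AP threshold: the voltage at which the dV/dt trajectory first reaches
  a slope criterion (default 10 mV/ms) on the rising phase of the spike.
- AP amplitude: membrane-potential difference between threshold and peak.
- AHP amplitude: difference between threshold and the most negative
  membrane potential attained during the afterhyperpolarization.
- Adaptation ratio: mean of the last two interspike intervals divided by
  the first interspike interval, for a 750-ms train at twice rheobase.
- Firing frequency: spike count of the same train divided by the step
  duration.
- Rheobase: the smallest step amplitude just sufficient to reach
  threshold for AP generation.
- Passive properties: input resistance from the steady-state V-I slope
  of hyperpolarizing steps, resting potential from the stimulus-free
  epoch, and the membrane time constant from a single-exponential fit
  to the step-onset relaxation.
- Recording QC: a cell is discarded when its access resistance changes
  by more than 20% over the session.

dV/dt is estimated by central differences on the raw sampled trace (an
optional Savitzky-Golay smoothing stage can be enabled for noisy data).
Undefined features propagate as NaN, never as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .errors import ClampModeError, DataError, RheobaseNotFoundError, ThresholdUndefinedError
from .sweeps import Sweep

__all__ = [
    "APFeatureSet",
    "TrainFeatureSet",
    "PassiveFeatureSet",
    "QCRecord",
    "RheobaseResult",
    "dvdt",
    "detect_spikes",
    "ap_threshold",
    "ap_waveform_features",
    "train_features",
    "find_rheobase",
    "passive_features",
    "qc_filter",
    "extract_cell_features",
]

DEFAULT_DVDT_CRITERION = 10.0  # mV/ms
DEFAULT_SPIKE_CUT = 0.0  # mV, absolute-voltage cut for peak detection
DEFAULT_REFRACTORY = 2.0  # ms, minimum peak separation
DEFAULT_AHP_WINDOW = 100.0  # ms, AHP search bound after the last spike
QC_MAX_CHANGE_PCT = 20.0  # access-resistance stability criterion


@dataclass
class APFeatureSet:
    """Per-spike waveform quantities.  Undefined entries are NaN."""

    threshold_time: float = np.nan  # ms
    threshold_voltage: float = np.nan  # mV
    peak_time: float = np.nan  # ms
    peak_voltage: float = np.nan  # mV
    amplitude: float = np.nan  # mV, peak - threshold
    ahp_minimum: float = np.nan  # mV
    ahp_amplitude: float = np.nan  # mV, threshold - AHP minimum
    ahp_decay_time: float = np.nan  # ms, peak -> AHP minimum
    max_upstroke: float = np.nan  # mV/ms
    max_downstroke: float = np.nan  # mV/ms


@dataclass
class TrainFeatureSet:
    """Per-train quantities for one current step."""

    n_spikes: int
    firing_frequency: float  # Hz
    adaptation_ratio: float  # NaN when n_spikes < 4
    delay_to_first_ap: float  # ms, step onset -> first AP threshold
    stimulus_amplitude: float  # pA
    per_spike: list[APFeatureSet] = field(default_factory=list)


@dataclass
class PassiveFeatureSet:
    input_resistance: float  # MOhm
    resting_potential: float  # mV
    membrane_time_constant: float  # ms


@dataclass
class QCRecord:
    """Access-resistance stability record for one cell."""

    cell_id: str
    access_resistance_series: list[float]  # MOhm over the session
    max_fractional_change: float = np.nan  # percent
    retained: bool = False


@dataclass
class RheobaseResult:
    rheobase: float  # pA
    rheobase_sweep: Sweep
    double_amplitude_sweep: Sweep | None
    double_is_exact: bool


# ---------------------------------------------------------------------------
# derivatives and spike detection
# ---------------------------------------------------------------------------

def dvdt(sweep: Sweep, smooth: bool = False) -> np.ndarray:
    """Central-difference dV/dt in mV/ms (optionally Savitzky-Golay smoothed V)."""
    v = sweep.samples
    if smooth:
        win = max(5, int(round(0.5 * sweep.sampling_rate)) | 1)
        v = savgol_filter(v, win, 3)
    return np.gradient(v, sweep.dt)


def detect_spikes(
    sweep: Sweep,
    cut: float = DEFAULT_SPIKE_CUT,
    refractory: float = DEFAULT_REFRACTORY,
) -> np.ndarray:
    """Spike peak times (ms): local maxima above ``cut`` separated by ``refractory``."""
    if sweep.clamp_mode != "current":
        raise ClampModeError("spike detection requires a current-clamp sweep")
    distance = max(1, int(round(refractory * sweep.sampling_rate)))
    idx, _ = find_peaks(sweep.samples, height=cut, distance=distance)
    return idx / sweep.sampling_rate


def _preceding_trough(v: np.ndarray, peak_idx: int, prev_bound: int) -> int:
    """Index of the minimum between the previous bound and this peak."""
    lo = max(prev_bound, 0)
    if lo >= peak_idx:
        return peak_idx
    return lo + int(np.argmin(v[lo:peak_idx]))


def ap_threshold(
    sweep: Sweep,
    peak_time: float,
    criterion: float = DEFAULT_DVDT_CRITERION,
    prev_peak_time: float | None = None,
    smooth: bool = False,
    interpolate: bool = False,
) -> tuple[float, float]:
    """Locate the AP threshold for the spike peaking at ``peak_time``.

    The threshold is the first sample of the rising-phase run on which
    dV/dt stays at or above ``criterion`` up to the peak, searched
    backward from the peak no further than the last subthreshold trough.
    With ``interpolate=True`` the exact criterion crossing is placed by
    linear interpolation between that sample and its predecessor.
    """
    if sweep.clamp_mode != "current":
        raise ClampModeError("threshold detection requires a current-clamp sweep")
    v = sweep.samples
    deriv = dvdt(sweep, smooth=smooth)
    peak_idx = sweep.time_to_index(peak_time)
    prev_bound = 0 if prev_peak_time is None else sweep.time_to_index(prev_peak_time)
    trough = _preceding_trough(v, peak_idx, prev_bound)
    window = deriv[trough : peak_idx + 1]
    above = window >= criterion
    if not above.any():
        raise ThresholdUndefinedError(
            f"no sample reaches {criterion} mV/ms before the peak at {peak_time:.3f} ms"
        )
    # last suprathreshold sample in the window, then rewind to the start of its run
    i = int(np.flatnonzero(above)[-1])
    while i > 0 and above[i - 1]:
        i -= 1
    thr_idx = trough + i
    t_thr = thr_idx * sweep.dt
    v_thr = v[thr_idx]
    if interpolate and thr_idx > 0 and deriv[thr_idx - 1] < criterion < deriv[thr_idx]:
        frac = (criterion - deriv[thr_idx - 1]) / (deriv[thr_idx] - deriv[thr_idx - 1])
        t_thr = (thr_idx - 1 + frac) * sweep.dt
        v_thr = v[thr_idx - 1] + frac * (v[thr_idx] - v[thr_idx - 1])
    return t_thr, float(v_thr)


def ap_waveform_features(
    sweep: Sweep,
    threshold: tuple[float, float],
    peak_time: float,
    next_threshold_time: float | None = None,
    ahp_window: float = DEFAULT_AHP_WINDOW,
    step_end: float | None = None,
) -> APFeatureSet:
    """Amplitude, AHP and stroke-slope features for one spike.

    The AHP is searched between the downward threshold-recrossing after
    the peak and the next spike's threshold; for the last spike the
    bound is ``ahp_window`` ms past the peak or the end of the step,
    whichever comes first.
    """
    v = sweep.samples
    deriv = dvdt(sweep)
    t_thr, v_thr = threshold
    peak_idx = sweep.time_to_index(peak_time)
    feats = APFeatureSet(
        threshold_time=t_thr,
        threshold_voltage=v_thr,
        peak_time=peak_time,
        peak_voltage=float(v[peak_idx]),
        amplitude=float(v[peak_idx]) - v_thr,
    )
    if next_threshold_time is not None:
        bound_t = next_threshold_time
    else:
        bound_t = peak_time + ahp_window
        if step_end is not None:
            bound_t = min(bound_t, step_end)
    bound_idx = min(sweep.time_to_index(bound_t), v.size - 1)
    after = v[peak_idx : bound_idx + 1]
    recross = np.flatnonzero(after <= v_thr)
    if recross.size == 0:
        return feats  # depolarization block: AHP undefined
    rc_idx = peak_idx + int(recross[0])
    ahp_rel = int(np.argmin(v[rc_idx : bound_idx + 1]))
    ahp_idx = rc_idx + ahp_rel
    feats.ahp_minimum = float(v[ahp_idx])
    feats.ahp_amplitude = v_thr - feats.ahp_minimum
    feats.ahp_decay_time = (ahp_idx - peak_idx) * sweep.dt
    thr_idx = sweep.time_to_index(t_thr)
    seg = deriv[thr_idx : ahp_idx + 1]
    if seg.size:
        feats.max_upstroke = float(seg.max())
        feats.max_downstroke = float(seg.min())
    return feats


# ---------------------------------------------------------------------------
# train-level features
# ---------------------------------------------------------------------------

def train_features(
    sweep: Sweep,
    criterion: float = DEFAULT_DVDT_CRITERION,
    cut: float = DEFAULT_SPIKE_CUT,
    refractory: float = DEFAULT_REFRACTORY,
    ahp_window: float = DEFAULT_AHP_WINDOW,
    delay_to: str = "threshold",
    smooth: bool = False,
) -> TrainFeatureSet:
    """Spike-train features for one current step.

    Only spikes whose peaks fall inside the stimulus epoch are counted.
    The adaptation ratio is defined only for trains of at least four
    spikes (three interspike intervals) and is NaN otherwise.
    ``delay_to`` selects whether the delay to the first AP is measured
    to its threshold (default) or to its peak.
    """
    if sweep.stimulus is None:
        raise DataError("train_features requires a sweep with a step stimulus")
    stim = sweep.stimulus
    peaks = detect_spikes(sweep, cut=cut, refractory=refractory)
    peaks = peaks[(peaks >= stim.onset) & (peaks <= stim.offset)]
    per_spike: list[APFeatureSet] = []
    thresholds: list[tuple[float, float] | None] = []
    for k, pt in enumerate(peaks):
        prev = peaks[k - 1] if k > 0 else None
        try:
            thresholds.append(
                ap_threshold(sweep, pt, criterion=criterion, prev_peak_time=prev,
                             smooth=smooth)
            )
        except ThresholdUndefinedError:
            thresholds.append(None)
    for k, pt in enumerate(peaks):
        thr = thresholds[k]
        if thr is None:
            per_spike.append(APFeatureSet(peak_time=pt,
                                          peak_voltage=float(
                                              sweep.samples[sweep.time_to_index(pt)])))
            continue
        nxt = None
        if k + 1 < len(peaks) and thresholds[k + 1] is not None:
            nxt = thresholds[k + 1][0]
        per_spike.append(
            ap_waveform_features(
                sweep, thr, pt,
                next_threshold_time=nxt,
                ahp_window=ahp_window,
                step_end=stim.offset if k == len(peaks) - 1 else None,
            )
        )
    n = len(peaks)
    freq = n / (stim.duration / 1000.0)
    if n >= 4:
        isis = np.diff(peaks)
        adaptation = float(np.mean(isis[-2:]) / isis[0])
    else:
        adaptation = np.nan
    if n:
        first = per_spike[0]
        ref = first.threshold_time if delay_to == "threshold" else first.peak_time
        delay = (ref if np.isfinite(ref) else first.peak_time) - stim.onset
    else:
        delay = np.nan
    return TrainFeatureSet(
        n_spikes=n,
        firing_frequency=freq,
        adaptation_ratio=adaptation,
        delay_to_first_ap=delay,
        stimulus_amplitude=stim.amplitude,
        per_spike=per_spike,
    )


def find_rheobase(
    sweeps: list[Sweep],
    cut: float = DEFAULT_SPIKE_CUT,
    refractory: float = DEFAULT_REFRACTORY,
) -> RheobaseResult:
    """Smallest step amplitude eliciting at least one AP within the step.

    Also returns the sweep at twice that amplitude, preferring an exact
    protocol match; ``double_is_exact`` is False when only a nearest
    neighbour exists.
    """
    depol = sorted(
        (sw for sw in sweeps if sw.stimulus is not None and sw.stimulus.amplitude > 0),
        key=lambda sw: sw.stimulus.amplitude,
    )
    rheo = None
    for sw in depol:
        peaks = detect_spikes(sw, cut=cut, refractory=refractory)
        stim = sw.stimulus
        if np.any((peaks >= stim.onset) & (peaks <= stim.offset)):
            rheo = sw
            break
    if rheo is None:
        raise RheobaseNotFoundError("no sweep in the protocol elicited an AP")
    target = 2.0 * rheo.stimulus.amplitude
    candidates = [sw for sw in depol if sw.stimulus.amplitude >= rheo.stimulus.amplitude]
    dbl = min(candidates, key=lambda sw: abs(sw.stimulus.amplitude - target), default=None)
    exact = dbl is not None and abs(dbl.stimulus.amplitude - target) < 1e-9
    return RheobaseResult(
        rheobase=rheo.stimulus.amplitude,
        rheobase_sweep=rheo,
        double_amplitude_sweep=dbl,
        double_is_exact=exact,
    )


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def _exp_relax(t, v_inf, dv, tau):
    return v_inf + dv * np.exp(-t / tau)


def passive_features(
    sweeps: list[Sweep],
    steady_fraction: float = 0.2,
    tau_guess: float = 20.0,
) -> PassiveFeatureSet:
    """Input resistance, resting potential and membrane time constant.

    Uses hyperpolarizing steps only; the steady-state window is the
    final ``steady_fraction`` of the step.  Sweeps containing spikes are
    excluded with a warning.  The time constant is fit on the sweep with
    the largest deflection.
    """
    hyper = [sw for sw in sweeps if sw.stimulus is not None and sw.stimulus.amplitude < 0]
    usable = []
    for sw in hyper:
        if detect_spikes(sw).size:
            warnings.warn(
                f"hyperpolarizing sweep at {sw.stimulus.amplitude} pA contains "
                "spikes; excluded from passive fits"
            )
            continue
        usable.append(sw)
    if not usable:
        raise DataError("passive_features requires at least one spike-free hyperpolarizing step")

    amps, dvs, rmps = [], [], []
    for sw in usable:
        stim = sw.stimulus
        i_on = sw.time_to_index(stim.onset)
        i_off = sw.time_to_index(stim.offset)
        i_steady = i_off - max(1, int(round(steady_fraction * (i_off - i_on))))
        rmp = float(np.mean(sw.samples[:i_on])) if i_on > 0 else float(sw.samples[0])
        rmps.append(rmp)
        dvs.append(float(np.mean(sw.samples[i_steady:i_off])) - rmp)
        amps.append(stim.amplitude)
    if len(usable) == 1:
        slope = dvs[0] / amps[0]  # mV/pA = GOhm
    else:
        slope = float(np.polyfit(amps, dvs, 1)[0])
    rin = slope * 1000.0  # MOhm

    big = usable[int(np.argmax(np.abs(dvs)))]
    stim = big.stimulus
    i_on = big.time_to_index(stim.onset)
    i_off = big.time_to_index(stim.offset)
    t = (np.arange(i_off - i_on)) * big.dt
    v = big.samples[i_on:i_off]
    try:
        popt, _ = curve_fit(
            _exp_relax, t, v,
            p0=(float(v[-1]), float(v[0] - v[-1]), tau_guess),
            maxfev=10000,
        )
        tau = float(abs(popt[2]))
    except RuntimeError:
        tau = np.nan
    return PassiveFeatureSet(
        input_resistance=rin,
        resting_potential=float(np.mean(rmps)),
        membrane_time_constant=tau,
    )


# ---------------------------------------------------------------------------
# recording QC
# ---------------------------------------------------------------------------

def qc_filter(record: QCRecord, max_change_pct: float = QC_MAX_CHANGE_PCT) -> QCRecord:
    """Apply the access-resistance stability rule (discard when > 20% change).

    The change is the largest fractional deviation from the first
    measurement, in percent.  Returns the record with
    ``max_fractional_change`` and ``retained`` filled in.
    """
    ra = np.asarray(record.access_resistance_series, dtype=float)
    if ra.size < 2:
        raise DataError("QC needs at least two access-resistance measurements")
    if np.any(ra <= 0):
        raise DataError("access resistance must be positive")
    change = float(np.max(np.abs(ra - ra[0]) / ra[0]) * 100.0)
    record.max_fractional_change = change
    record.retained = change <= max_change_pct
    return record


# ---------------------------------------------------------------------------
# per-cell roll-up
# ---------------------------------------------------------------------------

def extract_cell_features(
    sweeps: list[Sweep],
    criterion: float = DEFAULT_DVDT_CRITERION,
    **train_kwargs,
) -> dict:
    """One tidy feature row per cell from a full step family.

    First-AP waveform features come from the just-suprathreshold
    (rheobase) sweep; train features (firing frequency, adaptation
    ratio, delay) from the sweep at twice rheobase; passive features
    from the hyperpolarizing subset.
    """
    rheo = find_rheobase(sweeps)
    first_train = train_features(rheo.rheobase_sweep, criterion=criterion, **train_kwargs)
    row: dict = {"rheobase_pa": rheo.rheobase}
    if first_train.per_spike:
        ap = first_train.per_spike[0]
        row.update(
            threshold_mv=ap.threshold_voltage,
            peak_mv=ap.peak_voltage,
            amplitude_mv=ap.amplitude,
            ahp_amplitude_mv=ap.ahp_amplitude,
            ahp_decay_ms=ap.ahp_decay_time,
            max_upstroke_mv_ms=ap.max_upstroke,
            max_downstroke_mv_ms=ap.max_downstroke,
        )
    if rheo.double_amplitude_sweep is not None:
        dbl = train_features(rheo.double_amplitude_sweep, criterion=criterion, **train_kwargs)
        row.update(
            firing_frequency_hz=dbl.firing_frequency,
            adaptation_ratio=dbl.adaptation_ratio,
            delay_to_first_ap_ms=dbl.delay_to_first_ap,
            n_spikes_2x=dbl.n_spikes,
        )
    try:
        passive = passive_features(sweeps)
        row.update(
            input_resistance_mohm=passive.input_resistance,
            resting_potential_mv=passive.resting_potential,
            membrane_tau_ms=passive.membrane_time_constant,
        )
    except DataError:
        pass
    return row
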