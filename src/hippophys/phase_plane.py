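"""Phase-plane analysis of action potentials.

A phase trajectory plots dV/dt against V for one spike, from the
pre-spike trough to the AHP minimum.  Two summary statistics are
derived per train:

- threshold variation: spread (sample SD and range) of per-spike
  threshold voltages within one train at twice rheobase — a tightening
  of this spread is the maturation signature in the phase plots;
- onset rapidness: the slope of dV/dt versus V at the threshold
  crossing.  A steep slope marks the abrupt, biphasic spike onset
  ("kink") attributed to axon-initial-segment-first initiation; cells
  are flagged as kinked when the slope exceeds a configurable cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ephys import (
    DEFAULT_DVDT_CRITERION,
    TrainFeatureSet,
    dvdt,
)
from .errors import DataError
from .sweeps import Sweep

__all__ = [
    "PhaseTrajectory",
    "ThresholdVariationStats",
    "OnsetRapidness",
    "phase_trajectories",
    "threshold_variation",
    "onset_rapidness",
]

DEFAULT_KINK_CUTOFF = 10.0  # 1/ms


@dataclass
class PhaseTrajectory:
    """(V, dV/dt) pairs for one AP, trough to AHP minimum."""

    voltage: np.ndarray  # mV
    dvdt: np.ndarray  # mV/ms
    spike_index: int
    threshold_voltage: float  # mV

    def __len__(self) -> int:
        return self.voltage.size


@dataclass
class ThresholdVariationStats:
    thresholds: np.ndarray  # mV, per spike
    sd: float  # mV, sample SD (n-1)
    range: float  # mV


@dataclass
class OnsetRapidness:
    slope: float  # 1/ms, d(dV/dt)/dV at threshold
    kink: bool
    cutoff: float  # 1/ms


def phase_trajectories(sweep: Sweep, train: TrainFeatureSet) -> list[PhaseTrajectory]:
    """One phase-plane trajectory per AP with a defined threshold and AHP.

    The voltage axis uses the raw samples; the derivative uses the same
    central-difference estimator as the feature extractor, so each
    trajectory's dV/dt maximum equals that spike's max_upstroke.
    """
    deriv = dvdt(sweep)
    v = sweep.samples
    out: list[PhaseTrajectory] = []
    for k, ap in enumerate(train.per_spike):
        if not (np.isfinite(ap.threshold_time) and np.isfinite(ap.ahp_decay_time)):
            continue
        peak_idx = sweep.time_to_index(ap.peak_time)
        ahp_idx = peak_idx + int(round(ap.ahp_decay_time * sweep.sampling_rate))
        # walk back from threshold to the pre-spike trough
        thr_idx = sweep.time_to_index(ap.threshold_time)
        lo = thr_idx
        while lo > 0 and v[lo - 1] <= v[lo]:
            lo -= 1
        if ahp_idx - lo < 2:
            raise DataError(f"degenerate single-sample trajectory for spike {k}")
        out.append(
            PhaseTrajectory(
                voltage=v[lo : ahp_idx + 1].copy(),
                dvdt=deriv[lo : ahp_idx + 1].copy(),
                spike_index=k,
                threshold_voltage=ap.threshold_voltage,
            )
        )
    return out


def threshold_variation(train: TrainFeatureSet) -> ThresholdVariationStats | None:
    """Spread of per-spike threshold voltages within one train.

    Returns None when fewer than two spikes have a defined threshold.
    """
    thr = np.array(
        [ap.threshold_voltage for ap in train.per_spike if np.isfinite(ap.threshold_voltage)]
    )
    if thr.size < 2:
        return None
    return ThresholdVariationStats(
        thresholds=thr,
        sd=float(np.std(thr, ddof=1)),
        range=float(thr.max() - thr.min()),
    )


def onset_rapidness(
    trajectory: PhaseTrajectory,
    criterion: float = DEFAULT_DVDT_CRITERION,
    voltage_window: float = 1.0,
    cutoff: float = DEFAULT_KINK_CUTOFF,
) -> OnsetRapidness | None:
    """Least-squares slope of dV/dt vs V around the threshold crossing.

    The fit window spans ``voltage_window`` mV either side of the
    voltage at which the rising-phase dV/dt first reaches the slope
    criterion.  Returns None when fewer than three points fall in the
    window.  The kink flag is ``slope >= cutoff``.
    """
    v, d = trajectory.voltage, trajectory.dvdt
    peak_rel = int(np.argmax(v))
    rising = slice(0, peak_rel + 1)
    above = np.flatnonzero(d[rising] >= criterion)
    if above.size == 0:
        return None
    cross = above[0]
    v0 = v[cross]
    # restrict to the rising phase so the falling limb cannot enter the fit
    mask = np.abs(v[rising] - v0) <= voltage_window
    if np.count_nonzero(mask) < 3:
        return None
    slope = float(np.polyfit(v[rising][mask], d[rising][mask], 1)[0])
    return OnsetRapidness(slope=slope, kink=slope >= cutoff, cutoff=cutoff)
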