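"""The atomic recording unit: a single sweep, plus container IO.

A :class:`Sweep` holds one membrane-potential (current clamp) or
membrane-current (voltage clamp) time series together with the metadata
needed to interpret it: sampling rate in kHz, the stimulus epoch for a
current step, or the holding potential for voltage clamp.  Units follow
the electrophysiology convention used throughout the package: mV, ms,
pA, nS, pF, µm.

Sweeps are serialized to an HDF5 container (one group per sweep, the
time base implicit in a ``sampling_rate_khz`` attribute) and to plain
two-column CSV for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "StepStimulus",
    "Sweep",
    "write_sweeps_h5",
    "read_sweeps_h5",
    "write_sweep_csv",
    "read_sweep_csv",
]


@dataclass(frozen=True)
class StepStimulus:
    """A rectangular current step: onset and duration in ms, amplitude in pA."""

    onset: float
    duration: float
    amplitude: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Sweep:
    """One recorded trace with its acquisition metadata.

    Parameters
    ----------
    samples:
        Membrane potential (mV, current clamp) or current (pA, voltage
        clamp), sampled uniformly.
    sampling_rate:
        Sampling rate in kHz (samples per ms).
    clamp_mode:
        ``"current"`` or ``"voltage"``.
    stimulus:
        The current step, for current-clamp sweeps.
    holding_potential:
        Command potential in mV, for voltage-clamp sweeps.
    """

    samples: np.ndarray
    sampling_rate: float
    clamp_mode: str = "current"
    stimulus: StepStimulus | None = None
    holding_potential: float | None = None
    cell_id: str = ""
    age_group: str = ""
    cell_type: str = ""
    somatic_depth: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise DataError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.clamp_mode not in ("current", "voltage"):
            raise DataError(f"unknown clamp_mode {self.clamp_mode!r}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("sweep contains non-finite samples")
        if self.stimulus is not None:
            if self.stimulus.onset < 0 or self.stimulus.offset > self.duration + 1e-9:
                raise DataError("stimulus epoch extends beyond the trace span")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Trace duration in ms."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def time_to_index(self, t: float) -> int:
        return int(round(t * self.sampling_rate))

    def with_samples(self, samples: np.ndarray) -> "Sweep":
        return replace(self, samples=np.asarray(samples, dtype=float))


# ---------------------------------------------------------------------------
# HDF5 container: /sweeps/<name> datasets, metadata as attributes.
# ---------------------------------------------------------------------------

_OPTIONAL_ATTRS = ("cell_id", "age_group", "cell_type")


def write_sweeps_h5(path: str | Path, sweeps: Sequence[Sweep]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        for i, sw in enumerate(sweeps):
            ds = grp.create_dataset(f"sweep_{i:04d}", data=sw.samples)
            ds.attrs["sampling_rate_khz"] = sw.sampling_rate
            ds.attrs["clamp_mode"] = sw.clamp_mode
            for name in _OPTIONAL_ATTRS:
                ds.attrs[name] = getattr(sw, name)
            if sw.somatic_depth is not None:
                ds.attrs["somatic_depth"] = sw.somatic_depth
            if sw.stimulus is not None:
                ds.attrs["stim_onset_ms"] = sw.stimulus.onset
                ds.attrs["stim_duration_ms"] = sw.stimulus.duration
                ds.attrs["stim_amplitude_pa"] = sw.stimulus.amplitude
            if sw.holding_potential is not None:
                ds.attrs["holding_mv"] = sw.holding_potential


def read_sweeps_h5(path: str | Path) -> list[Sweep]:
    out: list[Sweep] = []
    with h5py.File(path, "r") as f:
        grp = f["sweeps"]
        for name in sorted(grp):
            ds = grp[name]
            attrs = dict(ds.attrs)
            if "sampling_rate_khz" not in attrs:
                raise DataError(f"sweep {name!r} lacks the sampling_rate_khz attribute")
            stim = None
            if "stim_onset_ms" in attrs:
                stim = StepStimulus(
                    float(attrs["stim_onset_ms"]),
                    float(attrs["stim_duration_ms"]),
                    float(attrs["stim_amplitude_pa"]),
                )
            out.append(
                Sweep(
                    samples=ds[()],
                    sampling_rate=float(attrs["sampling_rate_khz"]),
                    clamp_mode=str(attrs.get("clamp_mode", "current")),
                    stimulus=stim,
                    holding_potential=(
                        float(attrs["holding_mv"]) if "holding_mv" in attrs else None
                    ),
                    cell_id=str(attrs.get("cell_id", "")),
                    age_group=str(attrs.get("age_group", "")),
                    cell_type=str(attrs.get("cell_type", "")),
                    somatic_depth=(
                        float(attrs["somatic_depth"]) if "somatic_depth" in attrs else None
                    ),
                )
            )
    return out


def write_sweep_csv(path: str | Path, sweep: Sweep) -> None:
    """Two-column plain CSV: time (ms) and the recorded value."""
    value_name = "voltage_mv" if sweep.clamp_mode == "current" else "current_pa"
    pd.DataFrame({"time_ms": sweep.times, value_name: sweep.samples}).to_csv(
        path, index=False
    )


def read_sweep_csv(
    path: str | Path,
    clamp_mode: str = "current",
    stimulus: StepStimulus | None = None,
) -> Sweep:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    return Sweep(
        samples=df.iloc[:, 1].to_numpy(dtype=float),
        sampling_rate=1.0 / dt,
        clamp_mode=clamp_mode,
        stimulus=stimulus,
    )


def iter_sweeps(sweeps: Sequence[Sweep]) -> Iterator[tuple[int, Sweep]]:
    yield from enumerate(sweeps)
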