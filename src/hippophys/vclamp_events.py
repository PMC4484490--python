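"""Reversal potentials and postsynaptic-current event analysis.

Whole-cell voltage-clamp recordings separate excitatory from inhibitory
synaptic currents by holding the membrane above or below the computed
transmitter reversal potentials: at a holding of +40 mV (above both the
chloride and the mixed-cation reversal) all synaptic currents are
outward and inhibition dominates the record; at -80 mV (below both)
currents are inward and excitation dominates.

The chloride (GABA-A) reversal comes from the Nernst equation applied to
the free chloride of the pipette and bath solutions; only fully
dissociating salts (NaCl, KCl, CaCl2) contribute chloride.  The
glutamatergic reversal is fixed at 0 mV by configuration (mixed-cation
convention) rather than computed.

Events are detected by matched-filter correlation with a biexponential
template; the detection threshold is ``k`` times the MAD-based noise SD
of the filtered trace (default k = 4), with a minimum inter-event
interval for deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .errors import ClampModeError, ConfigError, DataError
from .sweeps import Sweep

__all__ = [
    "SolutionComposition",
    "ReversalSet",
    "PSCKernel",
    "PSCEvent",
    "INTRACELLULAR_SOLUTION",
    "RECORDING_ACSF",
    "EXC_KERNEL",
    "INH_KERNEL",
    "nernst_reversal",
    "reversal_set",
    "detect_psc_events",
    "classify_events",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol
DEFAULT_TEMPERATURE_C = 23.0  # room temperature midpoint

# Chloride stoichiometry of fully dissociating salts; buffers and large
# anions (HEPES, gluconate, EGTA, phosphate, sulfate) contribute none.
_CHLORIDE_STOICHIOMETRY = {"NaCl": 1, "KCl": 1, "CaCl2": 2, "MgCl2": 2, "HCl": 1}
_POTASSIUM_STOICHIOMETRY = {"KCl": 1, "K-gluconate": 1, "K2HPO4": 2}
_SODIUM_STOICHIOMETRY = {"NaCl": 1, "Na2HPO4": 2, "NaHCO3": 1, "GTP-Na": 1}


@dataclass(frozen=True)
class SolutionComposition:
    """Named salt concentrations (mM) with derived free-ion totals."""

    name: str
    salts: Mapping[str, float]
    temperature: float = DEFAULT_TEMPERATURE_C  # Celsius

    def __post_init__(self) -> None:
        for salt, conc in self.salts.items():
            if conc < 0:
                raise DataError(f"{self.name}: negative concentration for {salt}")
        object.__setattr__(self, "salts", dict(self.salts))

    def free_ion(self, ion: str) -> float:
        """Total free concentration (mM) of 'Cl', 'K' or 'Na'."""
        table = {
            "Cl": _CHLORIDE_STOICHIOMETRY,
            "K": _POTASSIUM_STOICHIOMETRY,
            "Na": _SODIUM_STOICHIOMETRY,
        }[ion]
        return sum(
            stoich * self.salts.get(salt, 0.0) for salt, stoich in table.items()
        )


# The pipette and bath recipes used for whole-cell recording (mM).
INTRACELLULAR_SOLUTION = SolutionComposition(
    "intracellular",
    {
        "K-gluconate": 135.0, "KCl": 10.0, "HEPES": 10.0,
        "ATP-Mg": 4.0, "GTP-Na": 0.3, "EGTA": 5.0,
    },
)
RECORDING_ACSF = SolutionComposition(
    "recording_aCSF",
    {
        "NaCl": 124.0, "KCl": 2.5, "Na2HPO4": 1.25, "CaCl2": 2.0,
        "MgSO4": 2.0, "NaHCO3": 26.0, "D-Glucose": 10.0,
    },
)


@dataclass(frozen=True)
class ReversalSet:
    """Computed reversal potentials used for event classification."""

    e_gaba: float  # mV, chloride Nernst potential
    e_glut: float  # mV, mixed-cation convention (configured, not computed)
    temperature: float  # Celsius


def nernst_reversal(
    inside: float, outside: float, valence: int, temperature: float = DEFAULT_TEMPERATURE_C
) -> float:
    """Nernst equilibrium potential E = (RT/zF) ln([out]/[in]) in mV."""
    if inside <= 0 or outside <= 0:
        raise DataError("Nernst concentrations must be positive")
    if valence == 0:
        raise DataError("valence must be nonzero")
    t_kelvin = temperature + 273.15
    return (
        1000.0
        * GAS_CONSTANT
        * t_kelvin
        / (valence * FARADAY)
        * np.log(outside / inside)
    )


def reversal_set(
    intracellular: SolutionComposition = INTRACELLULAR_SOLUTION,
    extracellular: SolutionComposition = RECORDING_ACSF,
    e_glut: float = 0.0,
    temperature: float | None = None,
) -> ReversalSet:
    """E_GABA from free chloride of the two solutions; E_glut by convention."""
    temp = temperature if temperature is not None else extracellular.temperature
    e_gaba = nernst_reversal(
        inside=intracellular.free_ion("Cl"),
        outside=extracellular.free_ion("Cl"),
        valence=-1,
        temperature=temp,
    )
    return ReversalSet(e_gaba=float(e_gaba), e_glut=e_glut, temperature=temp)


# ---------------------------------------------------------------------------
# PSC kernels and detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSCKernel:
    """Difference-of-exponentials PSC template, peak-normalized to 1."""

    rise: float  # ms
    decay: float  # ms

    def __post_init__(self) -> None:
        if not 0 < self.rise < self.decay:
            raise ConfigError("need 0 < rise < decay for a biexponential kernel")

    def waveform(self, sampling_rate: float, duration: float | None = None) -> np.ndarray:
        """Sampled template at ``sampling_rate`` kHz (length ~ 6 decay constants)."""
        if duration is None:
            duration = 6.0 * self.decay
        t = np.arange(0.0, duration, 1.0 / sampling_rate)
        w = np.exp(-t / self.decay) - np.exp(-t / self.rise)
        return w / w.max()

    @property
    def time_to_peak(self) -> float:
        r, d = self.rise, self.decay
        return r * d / (d - r) * np.log(d / r)


EXC_KERNEL = PSCKernel(rise=0.5, decay=5.0)
INH_KERNEL = PSCKernel(rise=1.0, decay=10.0)


@dataclass
class PSCEvent:
    onset_time: float  # ms
    amplitude: float  # pA, signed peak relative to baseline
    polarity: str  # "inward" | "outward"
    classification: str = "unclassified"  # excitatory | inhibitory | ambiguous
    holding_potential: float | None = None  # mV


def detect_psc_events(
    trace: Sweep,
    kernel: PSCKernel = EXC_KERNEL,
    k_mad: float = 4.0,
    min_interval: float = 5.0,
) -> list[PSCEvent]:
    """Matched-filter detection of postsynaptic currents of either polarity.

    The baseline-subtracted trace is correlated with the biexponential
    template; candidate events are local extrema of the filter output
    whose magnitude exceeds ``k_mad`` times the MAD-derived SD of the
    filtered trace, deduplicated by ``min_interval`` ms.  The reported
    amplitude is the signed extremum of the raw trace within one
    template length of the onset.
    """
    if trace.clamp_mode != "voltage":
        raise ClampModeError("PSC detection requires a voltage-clamp sweep")
    template = kernel.waveform(trace.sampling_rate)
    x = trace.samples
    if template.size > x.size:
        raise ConfigError("template longer than the trace")
    baseline = float(np.median(x))
    y = x - baseline
    # correlation = convolution with time-reversed template; normalize by energy
    score = fftconvolve(y, template[::-1], mode="valid") / np.dot(template, template)
    noise_sd = float(np.median(np.abs(score - np.median(score))) / 0.6744897501960817)
    if noise_sd == 0:
        noise_sd = np.finfo(float).tiny
    thresh = k_mad * noise_sd
    distance = max(1, int(round(min_interval * trace.sampling_rate)))
    events: list[tuple[int, float]] = []
    for sign in (+1.0, -1.0):
        # prominence at the same scale rejects noise bumps riding on the
        # decay shoulder of a preceding large event
        idx, _ = find_peaks(
            sign * score, height=thresh, distance=distance, prominence=thresh
        )
        events.extend((int(i), sign) for i in idx)
    events.sort()
    # cross-polarity deduplication: keep the stronger of two events closer
    # than min_interval
    kept: list[tuple[int, float]] = []
    for i, sign in events:
        if kept and i - kept[-1][0] < distance:
            if abs(score[i]) > abs(score[kept[-1][0]]):
                kept[-1] = (i, sign)
            continue
        kept.append((i, sign))

    out: list[PSCEvent] = []
    peak_off = int(round(kernel.time_to_peak * trace.sampling_rate))
    for i, sign in kept:
        lo = i
        hi = min(x.size, i + template.size)
        seg = y[lo:hi]
        amp = float(seg.max() if sign > 0 else seg.min())
        out.append(
            PSCEvent(
                onset_time=i / trace.sampling_rate,
                amplitude=amp,
                polarity="outward" if amp >= 0 else "inward",
                holding_potential=trace.holding_potential,
            )
        )
    return out


def classify_events(
    events: Sequence[PSCEvent],
    holding: float,
    reversals: ReversalSet,
) -> list[PSCEvent]:
    """Label events as excitatory / inhibitory / ambiguous.

    The convention follows the driving forces: at holdings above both
    reversals every physically possible synaptic current is outward and
    outward events are labelled inhibitory-dominant; below both
    reversals currents are inward and inward events are labelled
    excitatory-dominant.  Between the reversals, polarity decides:
    inward is consistent only with glutamatergic, outward only with
    GABAergic current.  Events whose polarity is inconsistent with both
    driving forces are ambiguous.
    """
    lo, hi = sorted((reversals.e_gaba, reversals.e_glut))
    for ev in events:
        inward = ev.amplitude < 0
        if holding >= hi:
            ev.classification = "inhibitory" if not inward else "ambiguous"
        elif holding <= lo:
            ev.classification = "excitatory" if inward else "ambiguous"
        else:
            # between the reversals: glutamatergic current is inward
            # (holding < e_glut), GABAergic current is outward
            # (holding > e_gaba) regardless of which reversal is higher
            below_glut = holding < reversals.e_glut
            above_gaba = holding > reversals.e_gaba
            if inward and below_glut:
                ev.classification = "excitatory"
            elif not inward and above_gaba:
                ev.classification = "inhibitory"
            else:
                ev.classification = "ambiguous"
        ev.holding_potential = holding
    return list(events)
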