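"""Built-in neuron presets and the preset registry.

Presets are calibrated so that features extracted from the simulated
sweeps fall in the physiological bands reported for the respective
recordings: naked-mole-rat hippocampal principal cells fire large
overshooting APs (peaks approaching but not exceeding +80 mV) at
11-16 Hz during a 750 ms step at twice rheobase, while juvenile mouse
CA1 cells show AP peaks of +40-45 mV.  The three naked-mole-rat age
variants additionally encode the maturation trends the analysis layer
is exercised on: younger cells have higher input resistance, larger
membrane noise (hence larger spike-threshold jitter) and weaker spike
currents; aged cells the converse.

Registered presets are immutable; ``register_preset`` refuses to
overwrite an existing name.  Custom registries can be loaded from a
JSON or YAML document mapping preset names to field dictionaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from ..errors import ConfigError
from .model import NeuronPreset

__all__ = [
    "BUILTIN_PRESETS",
    "get_preset",
    "register_preset",
    "available_presets",
    "load_preset_file",
    "dump_preset_file",
]


def _p(name, *, cm=150.0, gl=10.0, el=-70.0, gna, ena, gk, ek=-90.0, vt,
       gm, tau_max, noise) -> NeuronPreset:
    return NeuronPreset(
        name=name,
        membrane_capacitance=cm,
        leak_conductance=gl,
        leak_reversal=el,
        spike_channel_params={
            "gna": gna, "ena": ena, "gk": gk, "ek": ek, "vt": vt,
            "adaptation_tau_max": tau_max,
        },
        adaptation_strength=gm,
        noise_sd=noise,
    )


BUILTIN_PRESETS: dict[str, NeuronPreset] = {
    # Juvenile mouse CA1 pyramidal cell: moderate Na+ reversal keeps AP
    # peaks in the +40-45 mV range.
    "mouse": _p("mouse", gna=6000.0, ena=48.5, gk=1500.0, vt=-60.0,
                gm=15.0, tau_max=600.0, noise=0.3),
    # Naked mole rat, adult (1-year-like) CA1 pyramidal cell: the default
    # "naked_mole_rat" preset.  High Na+ reversal and conductance give
    # overshoots near +78 mV; the M-type conductance holds the 2x-rheobase
    # rate near 12 Hz.
    "naked_mole_rat": _p("naked_mole_rat", gna=12000.0, ena=80.0, gk=1600.0,
                         vt=-60.0, gm=12.0, tau_max=800.0, noise=0.3),
    # Young (4-month-like): higher input resistance, weaker spike currents,
    # larger membrane noise -> larger threshold jitter, immature phenotype.
    "naked_mole_rat_young": _p("naked_mole_rat_young", gl=6.0, gna=9000.0,
                               ena=80.0, gk=1400.0, vt=-58.0, gm=10.0,
                               tau_max=800.0, noise=0.9),
    # Aged (8-10-year-like): lower input resistance, strong spike currents,
    # low noise -> tight thresholds and reliable trains.
    "naked_mole_rat_aged": _p("naked_mole_rat_aged", gl=12.0, gna=14000.0,
                              ena=80.0, gk=1700.0, vt=-61.0, gm=16.0,
                              tau_max=800.0, noise=0.15),
}

_REGISTRY: dict[str, NeuronPreset] = dict(BUILTIN_PRESETS)


def get_preset(name: str) -> NeuronPreset:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_preset(preset: NeuronPreset, overwrite: bool = False) -> None:
    if preset.name in _REGISTRY and not overwrite:
        raise ConfigError(f"preset {preset.name!r} already registered")
    _REGISTRY[preset.name] = preset


def available_presets() -> list[str]:
    return sorted(_REGISTRY)


def _preset_to_dict(p: NeuronPreset) -> dict:
    return {
        "membrane_capacitance": p.membrane_capacitance,
        "leak_conductance": p.leak_conductance,
        "leak_reversal": p.leak_reversal,
        "spike_channel_params": dict(p.spike_channel_params),
        "adaptation_strength": p.adaptation_strength,
        "noise_sd": p.noise_sd,
    }


def load_preset_file(path: str | Path, register: bool = False) -> dict[str, NeuronPreset]:
    """Read a JSON/YAML preset document ``{name: {field: value, ...}}``."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: preset document must be a mapping")
    out = {}
    for name, fields in doc.items():
        out[name] = NeuronPreset(name=name, **fields)
        if register:
            register_preset(out[name], overwrite=True)
    return out


def dump_preset_file(path: str | Path, presets: dict[str, NeuronPreset] | None = None) -> None:
    presets = presets if presets is not None else _REGISTRY
    doc = {name: _preset_to_dict(p) for name, p in presets.items()}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
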