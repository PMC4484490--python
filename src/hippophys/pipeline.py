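"""End-to-end orchestration: simulate → extract → phase → vclamp → morpho → compare.

The demo cohort mirrors the study layout: three age groups of
simulated cells (a young, an adult and an aged preset), each recorded
with a family of hyperpolarizing and depolarizing 750-ms current steps,
voltage-clamp epochs at +40 and −80 mV, and one reconstructed
morphology per cell.  Every stage writes plain tabular outputs under
the run directory, and a manifest records the configuration hash, the
seed of every stochastic call and per-stage runtimes, so a run is
byte-reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ephys, group_stats, morphometry, phase_plane, vclamp_events
from .errors import ConfigError, HippophysError, SWCParseError
from .sweeps import Sweep, read_sweeps_h5, write_sweeps_h5
from .synthgen import (
    MorphoGenParams,
    StimulusProtocol,
    generate_morphology,
    get_preset,
    simulate_current_clamp,
    simulate_voltage_clamp,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "run_stage", "validate_inputs"]

STAGES = ("simulate", "extract", "phase", "vclamp", "morpho", "compare")

# age group -> (neuron preset, morphology scale factor)
DEFAULT_GROUPS: dict[str, str] = {
    "4_months": "naked_mole_rat_young",
    "1_year": "naked_mole_rat",
    "8_10_years": "naked_mole_rat_aged",
}
_MORPHO_BY_GROUP = {
    "4_months": MorphoGenParams(trunk_length_mean=60.0, branch_probability=0.006,
                                segment_length_mean=40.0, segment_length_sd=12.0,
                                max_depth=3, n_stems=2),
    "1_year": MorphoGenParams(trunk_length_mean=90.0, branch_probability=0.012,
                              segment_length_mean=60.0, segment_length_sd=18.0,
                              max_depth=5, n_stems=3),
    "8_10_years": MorphoGenParams(trunk_length_mean=110.0, branch_probability=0.016,
                                  segment_length_mean=75.0, segment_length_sd=20.0,
                                  max_depth=6, n_stems=3),
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    sampling_rate: float = 20.0  # kHz
    dvdt_criterion: float = 10.0  # mV/ms
    step_duration: float = 750.0  # ms
    qc_threshold: float = 20.0  # percent access-resistance change
    alpha: float = 0.05
    cells_per_group: int = 5
    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    step_increment: float = 25.0  # pA
    max_step: float = 400.0  # pA
    hyper_steps: tuple[float, ...] = (-50.0, -25.0)
    pre_step: float = 100.0  # ms
    post_step: float = 50.0  # ms
    vclamp_duration: float = 5.0  # s per holding
    vclamp_exc_rate: float = 4.0  # Hz
    vclamp_inh_rate: float = 2.0  # Hz
    n_qc_fail_per_group: int = 1  # injected unstable-access cells
    depth_rm_gain: float = 0.4  # leak scaling vs somatic depth

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "dvdt_criterion", "step_duration",
                     "qc_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        self.hyper_steps = tuple(self.hyper_steps)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hyper_steps"] = list(d["hyper_steps"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    stage_runtime_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _protocol(cfg: RunConfig) -> StimulusProtocol:
    depol = tuple(np.arange(cfg.step_increment, cfg.max_step + 1e-9, cfg.step_increment))
    return StimulusProtocol(
        step_amplitudes=cfg.hyper_steps + depol,
        pre_step_duration=cfg.pre_step,
        step_duration=cfg.step_duration,
        post_step_duration=cfg.post_step,
        sampling_rate=cfg.sampling_rate,
    )


def _cell_seed(base: int, group_idx: int, cell_idx: int, channel: int = 0) -> int:
    # stable per-cell sub-seed below 2**31
    return int((base * 1_000_003 + group_idx * 10_007 + cell_idx * 101 + channel)
               % (2**31 - 1))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run all stages on the synthetic cohort; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_hash=config.digest())
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    current_stage = "simulate"
    try:
        for stage in STAGES:
            current_stage = stage
            t0 = time.perf_counter()
            globals()[f"_stage_{stage}"](config, out, manifest)
            manifest.stage_runtime_s[stage] = round(time.perf_counter() - t0, 3)
            manifest.write(out / "manifest.json")
    except HippophysError as exc:
        manifest.write(out / "manifest.json")
        raise HippophysError(f"stage {current_stage!r} failed: {exc}") from exc
    return manifest


def run_stage(stage: str, config: RunConfig) -> RunManifest:
    """Run one named stage against ``config.out_dir``.

    Later stages read the outputs of earlier ones from the run
    directory, so prerequisites must already exist there.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; stages are {list(STAGES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_hash=config.digest())
    t0 = time.perf_counter()
    globals()[f"_stage_{stage}"](config, out, manifest)
    manifest.stage_runtime_s[stage] = round(time.perf_counter() - t0, 3)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _cells(config: RunConfig):
    for gi, (group, preset_name) in enumerate(config.groups.items()):
        for ci in range(config.cells_per_group):
            yield gi, group, preset_name, ci, f"{group}_cell{ci:02d}"


def _stage_simulate(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    proto = _protocol(config)
    sim_dir = out / "sweeps"
    sim_dir.mkdir(exist_ok=True)
    meta_rows = []
    for gi, group, preset_name, ci, cell_id in _cells(config):
        preset = get_preset(preset_name)
        seed = _cell_seed(config.seed, gi, ci)
        rng = np.random.default_rng(seed)
        depth = float(rng.uniform(0.0, 1.0))
        # deeper cells are less mature: scale the leak down with depth
        gl = preset.leak_conductance * (1.0 - config.depth_rm_gain * (depth - 0.5))
        preset = dataclasses.replace(preset, leak_conductance=gl)
        rec = simulate_current_clamp(preset, proto, seed=seed)
        for sw in rec.sweeps:
            sw.cell_id, sw.age_group, sw.cell_type = cell_id, group, "CA1_pyramidal"
            sw.somatic_depth = depth
        path = sim_dir / f"{cell_id}.h5"
        write_sweeps_h5(path, rec.sweeps)
        manifest.seeds[f"simulate/{cell_id}"] = seed
        manifest.outputs.append(str(path))
        # synthetic access-resistance session: first cells per group are
        # stable, the last n_qc_fail_per_group drift past the QC bound
        fail = ci >= config.cells_per_group - config.n_qc_fail_per_group
        drift = rng.uniform(0.25, 0.35) if fail else rng.uniform(0.0, 0.10)
        ra0 = rng.uniform(8.0, 15.0)
        ra = [ra0, ra0 * (1 + drift / 2), ra0 * (1 + drift)]
        meta_rows.append(
            {"cell_id": cell_id, "age_group": group, "somatic_depth": depth,
             "ra_series_mohm": json.dumps([round(r, 3) for r in ra])}
        )
    pd.DataFrame(meta_rows).to_csv(out / "cells.csv", index=False)
    manifest.outputs.append(str(out / "cells.csv"))


def _stage_extract(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    cells = pd.read_csv(out / "cells.csv")
    rows, qc_rows = [], []
    for rec in cells.itertuples():
        ra = json.loads(rec.ra_series_mohm)
        qc = ephys.qc_filter(
            ephys.QCRecord(cell_id=rec.cell_id, access_resistance_series=ra),
            max_change_pct=config.qc_threshold,
        )
        qc_rows.append(
            {"cell_id": rec.cell_id, "max_fractional_change_pct": qc.max_fractional_change,
             "retained": qc.retained}
        )
        if not qc.retained:
            continue
        sweeps = read_sweeps_h5(out / "sweeps" / f"{rec.cell_id}.h5")
        row = {"cell_id": rec.cell_id, "age_group": rec.age_group,
               "somatic_depth": rec.somatic_depth}
        row.update(ephys.extract_cell_features(sweeps, criterion=config.dvdt_criterion))
        rows.append(row)
    pd.DataFrame(qc_rows).to_csv(out / "qc_log.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    manifest.outputs += [str(out / "qc_log.csv"), str(out / "features.csv")]


def _stage_phase(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    feats = pd.read_csv(out / "features.csv")
    rows, long_rows = [], []
    for rec in feats.itertuples():
        sweeps = read_sweeps_h5(out / "sweeps" / f"{rec.cell_id}.h5")
        rheo = ephys.find_rheobase(sweeps)
        if rheo.double_amplitude_sweep is None:
            continue
        sw = rheo.double_amplitude_sweep
        train = ephys.train_features(sw, criterion=config.dvdt_criterion)
        trajs = phase_plane.phase_trajectories(sw, train)
        var = phase_plane.threshold_variation(train)
        kinks = [
            phase_plane.onset_rapidness(tr, criterion=config.dvdt_criterion)
            for tr in trajs
        ]
        kinks = [k for k in kinks if k is not None]
        rows.append(
            {
                "cell_id": rec.cell_id,
                "age_group": rec.age_group,
                "threshold_sd_mv": var.sd if var else np.nan,
                "threshold_range_mv": var.range if var else np.nan,
                "onset_rapidness_per_ms": (
                    float(np.mean([k.slope for k in kinks])) if kinks else np.nan
                ),
                "kink_fraction": (
                    float(np.mean([k.kink for k in kinks])) if kinks else np.nan
                ),
            }
        )
        for tr in trajs:
            for v, d in zip(tr.voltage, tr.dvdt):
                long_rows.append(
                    {"cell_id": rec.cell_id, "spike_index": tr.spike_index,
                     "v_mv": v, "dvdt_mv_ms": d}
                )
    pd.DataFrame(rows).to_csv(out / "phase_summary.csv", index=False)
    pd.DataFrame(long_rows).to_csv(out / "phase_trajectories.csv", index=False)
    manifest.outputs += [str(out / "phase_summary.csv"), str(out / "phase_trajectories.csv")]


def _stage_vclamp(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    reversals = vclamp_events.reversal_set()
    rows = []
    for gi, (group, _preset) in enumerate(config.groups.items()):
        for holding in (40.0, -80.0):
            seed = _cell_seed(config.seed, gi, 900 + int(holding), channel=1)
            rec = simulate_voltage_clamp(
                holding, config.vclamp_exc_rate, config.vclamp_inh_rate,
                config.vclamp_duration, seed=seed,
                sampling_rate=config.sampling_rate,
            )
            manifest.seeds[f"vclamp/{group}/{holding:+.0f}mV"] = seed
            events = vclamp_events.detect_psc_events(rec.sweeps[0])
            events = vclamp_events.classify_events(events, holding, reversals)
            for ev in events:
                rows.append(
                    {"age_group": group, "holding_mv": holding,
                     "onset_ms": ev.onset_time, "amplitude_pa": ev.amplitude,
                     "polarity": ev.polarity, "classification": ev.classification}
                )
    pd.DataFrame(rows).to_csv(out / "psc_events.csv", index=False)
    (out / "reversals.json").write_text(
        json.dumps({"e_gaba_mv": reversals.e_gaba, "e_glut_mv": reversals.e_glut,
                    "temperature_c": reversals.temperature}, indent=2)
    )
    manifest.outputs += [str(out / "psc_events.csv"), str(out / "reversals.json")]


def _stage_morpho(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    swc_dir = out / "swc"
    swc_dir.mkdir(exist_ok=True)
    rows = []
    for gi, group, _preset, ci, cell_id in _cells(config):
        params = _MORPHO_BY_GROUP.get(group, MorphoGenParams())
        seed = _cell_seed(config.seed, gi, ci, channel=2)
        gen = generate_morphology(params, seed=seed)
        manifest.seeds[f"morpho/{cell_id}"] = seed
        path = swc_dir / f"{cell_id}.swc"
        morphometry.write_swc(gen.tree, path)
        summ = morphometry.summarize_morphology(gen.tree)
        rows.append(
            {"cell_id": cell_id, "age_group": group,
             "n_segments": summ.n_segments,
             "total_length_um": summ.total_length,
             "maximal_length_um": summ.maximal_length,
             "mean_segment_length_um": summ.mean_segment_length,
             "max_branch_order": summ.max_branch_order}
        )
        manifest.outputs.append(str(path))
    pd.DataFrame(rows).to_csv(out / "morphometry.csv", index=False)
    manifest.outputs.append(str(out / "morphometry.csv"))


def _stage_compare(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    feats = pd.read_csv(out / "features.csv")
    phase = pd.read_csv(out / "phase_summary.csv")
    morpho = pd.read_csv(out / "morphometry.csv")
    table = feats.merge(phase.drop(columns=["age_group"]), on="cell_id", how="left")
    table = table.merge(morpho.drop(columns=["age_group"]), on="cell_id", how="left")
    log: list[str] = []
    report = group_stats.compare_ages(
        table.drop(columns=["cell_id", "somatic_depth"]),
        group_key="age_group", alpha=config.alpha, log=log,
    )
    report.to_csv(out / "comparison_report.csv", index=False)
    report.to_json(out / "comparison_report.json", orient="records", indent=2)
    (out / "comparison_log.txt").write_text("\n".join(log) + ("\n" if log else ""))
    manifest.outputs += [
        str(out / "comparison_report.csv"),
        str(out / "comparison_report.json"),
    ]


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: list[str | Path]) -> list[dict]:
    """Schema/integrity checks; returns a list of issue records (never raises)."""
    issues: list[dict] = []
    for p in map(Path, paths):
        if not p.exists():
            issues.append({"path": str(p), "issue": "file not found"})
            continue
        if p.suffix == ".swc":
            try:
                morphometry.read_swc(p)
            except SWCParseError as exc:
                issues.append({"path": str(p), "issue": str(exc)})
        elif p.suffix in (".h5", ".hdf5"):
            try:
                read_sweeps_h5(p)
            except Exception as exc:  # missing attrs, bad schema
                issues.append({"path": str(p), "issue": str(exc)})
        else:
            issues.append({"path": str(p), "issue": "unrecognized input type"})
    return issues
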