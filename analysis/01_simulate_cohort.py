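#!/usr/bin/env python
"""Simulate the synthetic cohort: three age groups of hippocampal cells.

Each cell gets a full current-step family (−50 to +450 pA, 750 ms steps,
20 kHz), a somatic-depth covariate that modulates its leak conductance
(deeper = less mature = higher input resistance), and a synthetic
access-resistance session; one cell per group is injected with an
unstable access resistance so the QC rule has something to reject.
Writes sweeps (HDF5), cells.csv and the run manifest under
results/cohort/.
"""

from pathlib import Path

from common import cohort_config, parse_args

from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = run_stage("simulate", cfg)
    manifest.write(out / "manifest.json")
    n = cfg.cells_per_group * len(cfg.groups)
    print(f"simulated {n} cells ({cfg.cells_per_group} per group x "
          f"{len(cfg.groups)} age groups) -> {out}")
    print(f"injected {cfg.n_qc_fail_per_group} QC-failing cell(s) per group")


if __name__ == "__main__":
    main()
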