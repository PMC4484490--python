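#!/usr/bin/env python
"""Voltage-clamp epochs at +40 and −80 mV: detect and classify PSCs.

Computes the chloride (GABA-A) reversal from the pipette/bath recipes
via the Nernst equation, simulates 5-s voltage-clamp epochs with mixed
Poisson excitatory/inhibitory input for each age group, detects events
by matched filtering, and classifies them against the reversals.
Writes psc_events.csv and reversals.json.
"""

import json
from pathlib import Path

import pandas as pd
from common import cohort_config, parse_args

from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    run_stage("vclamp", cfg)
    rev = json.loads((out / "reversals.json").read_text())
    print(f"computed reversals: E_GABA = {rev['e_gaba_mv']:.1f} mV (chloride Nernst), "
          f"E_glut = {rev['e_glut_mv']:.1f} mV (convention), "
          f"{rev['temperature_c']:.0f} C")
    events = pd.read_csv(out / "psc_events.csv")
    table = events.groupby(["holding_mv", "classification"]).size().unstack(fill_value=0)
    print("detected events by holding potential:")
    print(table.to_string())


if __name__ == "__main__":
    main()
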