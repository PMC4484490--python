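#!/usr/bin/env python
"""Phase-plane analysis of the 2x-rheobase trains.

For every retained cell: per-spike (V, dV/dt) trajectories, the spread
of per-spike threshold voltages within the train (the quantity that
tightens with maturation), and onset rapidness with the kink flag.
Writes phase_summary.csv and the long-format trajectories.
"""

from pathlib import Path

import pandas as pd
from common import cohort_config, parse_args

from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    run_stage("phase", cfg)
    summ = pd.read_csv(out / "phase_summary.csv")
    by_group = summ.groupby("age_group")[
        ["threshold_sd_mv", "onset_rapidness_per_ms", "kink_fraction"]
    ].mean().round(3)
    print("per-group phase-plane summary (means):")
    print(by_group.to_string())
    tightest = by_group.threshold_sd_mv.idxmin()
    print(f"threshold variation is tightest in the {tightest!r} group")


if __name__ == "__main__":
    main()
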