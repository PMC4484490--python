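#!/usr/bin/env python
"""Apply the recording QC rule and extract the per-cell feature table.

Cells whose access resistance changed by more than 20% are discarded
(qc_log.csv records every decision).  For each retained cell: first-AP
waveform features at rheobase, train features (firing frequency,
adaptation ratio, delay to first AP) at twice rheobase, and passive
properties from the hyperpolarizing steps.  Writes features.csv.
"""

from pathlib import Path

import pandas as pd
from common import cohort_config, parse_args

from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    run_stage("extract", cfg)
    qc = pd.read_csv(out / "qc_log.csv")
    feats = pd.read_csv(out / "features.csv")
    print(f"QC: {int(qc.retained.sum())}/{len(qc)} cells retained "
          f"(threshold {cfg.qc_threshold:.0f}% access-resistance change)")
    summary = feats.groupby("age_group")[
        ["rheobase_pa", "firing_frequency_hz", "peak_mv",
         "input_resistance_mohm", "adaptation_ratio"]
    ].mean().round(2)
    print("group means:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
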