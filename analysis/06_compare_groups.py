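#!/usr/bin/env python
"""Nonparametric age comparison across all extracted features.

Merges the electrophysiological, phase-plane and morphometric feature
tables and runs every pairwise Mann-Whitney U comparison between age
groups (two-sided, exact p for small samples, alpha = 0.05, no
multiplicity adjustment).  Writes comparison_report.csv/.json and
prints the significant differences.
"""

from pathlib import Path

import pandas as pd
from common import cohort_config, parse_args

from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    run_stage("compare", cfg)
    report = pd.read_csv(out / "comparison_report.csv")
    sig = report[report.significant]
    print(f"{len(sig)}/{len(report)} pairwise comparisons significant at "
          f"alpha = {cfg.alpha}")
    cols = ["feature", "group1", "group2", "n1", "n2", "U", "p"]
    print(sig[cols].to_string(index=False))


if __name__ == "__main__":
    main()
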