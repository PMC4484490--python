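#!/usr/bin/env python
"""Dendritic morphometry of the cohort's reconstructed trees.

Generates one SWC reconstruction per cell (age-dependent branching
statistics), then measures segment count, total and maximal dendrite
length, and branch order.  Also correlates input resistance with
somatic depth across the cohort's granule-layer-style covariate.
Writes morphometry.csv and per-cell SWC files.
"""

from pathlib import Path

import pandas as pd
from common import cohort_config, parse_args

from hippophys.morphometry import depth_feature_correlation
from hippophys.pipeline import run_stage


def main() -> None:
    args = parse_args(__doc__)
    cfg = cohort_config(args.seed)
    out = Path(cfg.out_dir)
    run_stage("morpho", cfg)
    morpho = pd.read_csv(out / "morphometry.csv")
    print("morphometry by age group (means):")
    print(morpho.groupby("age_group")[
        ["n_segments", "total_length_um", "maximal_length_um", "max_branch_order"]
    ].mean().round(1).to_string())

    feats = pd.read_csv(out / "features.csv")
    pairs = list(zip(feats.somatic_depth, feats.input_resistance_mohm))
    rho, p = depth_feature_correlation(pairs)
    print(f"somatic depth vs input resistance: Spearman rho = {rho:.2f}, p = {p:.3g} "
          f"(n = {len(pairs)})")


if __name__ == "__main__":
    main()
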