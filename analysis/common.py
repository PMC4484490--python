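"""Shared configuration for the numbered analysis drivers.

Every driver operates on the same run directory (``results/cohort`` by
default) with the cohort layout produced by ``01_simulate_cohort.py``:
three age groups of simulated naked-mole-rat hippocampal cells, five
cells each, one injected access-resistance-unstable cell per group.
"""

import argparse
from pathlib import Path

from hippophys.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def cohort_config(seed: int) -> RunConfig:
    return RunConfig(seed=seed, out_dir=str(RESULTS / "cohort"), cells_per_group=5)


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1)
    return p.parse_args()
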