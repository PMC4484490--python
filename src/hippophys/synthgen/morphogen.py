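"""Stochastic dendritic-tree generator with exact ground truth.

Trees grow from a spherical soma as a branching random walk: each
segment is a chain of ~10 µm internodes with slightly wandering
direction; at a segment's distal end it either terminates or splits
into ``daughter_count`` children, with a branching probability set by a
per-µm rate integrated over the segment length.  The trunk (first
segment of each stem) has deterministic length ``trunk_length_mean`` so
degenerate configurations stay exactly analyzable; deeper segment
lengths are drawn from a clipped normal.

Ground truth (total dendritic length, segment count, longest
soma-to-tip path, maximal branch order) is accumulated from the actual
node coordinates during generation, so the morphometry module must
reproduce it to floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError, EmptyMorphologyError
from ..morphometry import (
    APICAL_DENDRITE,
    SOMA,
    MorphologyTree,
    SWCNode,
)

__all__ = ["MorphoGenParams", "GeneratedMorphology", "generate_morphology"]


@dataclass(frozen=True)
class MorphoGenParams:
    trunk_length_mean: float = 80.0  # µm, deterministic stem length
    branch_probability: float = 0.008  # per µm branching rate
    daughter_count: int = 2
    segment_length_mean: float = 60.0  # µm
    segment_length_sd: float = 20.0  # µm
    max_depth: int = 5  # branch orders
    n_stems: int = 1
    internode_step: float = 10.0  # µm between SWC points
    wobble_sd: float = 0.15  # radians of direction drift per internode

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_probability:
            raise ConfigError("branch_probability rate must be >= 0")
        if self.trunk_length_mean <= 0 or self.segment_length_mean <= 0:
            raise ConfigError("lengths must be positive")
        if self.daughter_count < 1 or self.max_depth < 1 or self.n_stems < 1:
            raise ConfigError("counts must be >= 1")


@dataclass
class GeneratedMorphology:
    tree: MorphologyTree
    # ground truth recorded during generation
    total_length: float  # µm
    n_segments: int
    maximal_length: float  # µm, longest soma-to-tip path
    max_branch_order: int
    seed: int


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _wobble(direction: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0:
        return direction
    return _unit(direction + rng.normal(0.0, sd, size=3))


def _rotate_away(direction: np.ndarray, rng: np.random.Generator, angle: float) -> np.ndarray:
    """A daughter direction at roughly ``angle`` radians from the parent."""
    # random perpendicular component
    r = rng.normal(size=3)
    perp = r - np.dot(r, direction) * direction
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        perp = np.array([direction[1], -direction[0], 0.0])
        norm = np.linalg.norm(perp)
    perp /= norm
    return _unit(np.cos(angle) * direction + np.sin(angle) * perp)


def generate_morphology(params: MorphoGenParams, seed: int) -> GeneratedMorphology:
    """Grow one tree; deterministic (byte-identical SWC) for a fixed seed."""
    rng = np.random.default_rng(seed)
    nodes: dict[int, SWCNode] = {1: SWCNode(1, SOMA, 0.0, 0.0, 0.0, 6.0, -1)}
    next_id = 2
    total = 0.0
    n_segments = 0
    maximal = 0.0
    max_order = 0

    # (parent node id, position, direction, order, soma->start path length)
    stack: list[tuple[int, np.ndarray, np.ndarray, int, float]] = []
    for _ in range(params.n_stems):
        stack.append(
            (1, np.zeros(3), _unit(rng.normal(size=3)), 1, 0.0)
        )

    while stack:
        parent_id, pos, direction, order, path0 = stack.pop()
        if order == 1:
            seg_len = params.trunk_length_mean
        else:
            seg_len = max(
                rng.normal(params.segment_length_mean, params.segment_length_sd),
                params.internode_step,
            )
        # lay internodes; final partial step keeps total exactly seg_len
        remaining = seg_len
        realized = 0.0
        cur_parent = parent_id
        while remaining > 1e-12:
            step = min(params.internode_step, remaining)
            direction = _wobble(direction, rng, params.wobble_sd)
            pos = pos + direction * step
            nodes[next_id] = SWCNode(
                next_id, APICAL_DENDRITE,
                float(pos[0]), float(pos[1]), float(pos[2]), 0.6, cur_parent,
            )
            cur_parent = next_id
            next_id += 1
            remaining -= step
            realized += step
        total += realized
        n_segments += 1
        max_order = max(max_order, order)
        tip_path = path0 + realized

        branch_p = 1.0 - np.exp(-params.branch_probability * realized)
        branches = order < params.max_depth and rng.random() < branch_p
        if branches:
            for _ in range(params.daughter_count):
                angle = rng.uniform(0.3, 0.7)  # ~17-40 degrees off the parent
                stack.append(
                    (cur_parent, pos.copy(), _rotate_away(direction, rng, angle),
                     order + 1, tip_path)
                )
        else:
            maximal = max(maximal, tip_path)

    if n_segments == 0 or len(nodes) < 2:
        raise EmptyMorphologyError("generator parameters produced an empty tree")

    tree = MorphologyTree(nodes)
    return GeneratedMorphology(
        tree=tree,
        total_length=total,
        n_segments=n_segments,
        maximal_length=maximal,
        max_branch_order=max_order,
        seed=seed,
    )
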