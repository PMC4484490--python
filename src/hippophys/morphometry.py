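"""SWC-based dendritic morphometry.

Reconstructed neurons arrive as standard 7-column SWC files (id, type,
x, y, z, radius, parent; '#' comments allowed; one root with parent -1).
The morphometric unit is the *segment*: a maximal unbranched path
between the soma, a branch point, or a terminal — the same granularity
as filament-tracing software reports.  Per-cell summaries cover the
quantities used in the age comparison: number of dendrite segments,
total dendritic length, maximal dendrite length (read as the longest
soma-to-tip path), mean/max segment length and maximal branch order.

Axonal nodes (SWC type 2) are excluded from dendritic summaries by
default.  A rank-correlation helper relates somatic depth in the
granule-cell layer to any extracted feature (Spearman rho, exact
permutation p for small n).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, SWCParseError

__all__ = [
    "SWCNode",
    "MorphologyTree",
    "Segment",
    "SegmentTable",
    "MorphoSummary",
    "read_swc",
    "write_swc",
    "decompose_segments",
    "summarize_morphology",
    "depth_feature_correlation",
]

SOMA, AXON, BASAL_DENDRITE, APICAL_DENDRITE = 1, 2, 3, 4
DENDRITE_TYPES = frozenset({BASAL_DENDRITE, APICAL_DENDRITE})


@dataclass(frozen=True)
class SWCNode:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class MorphologyTree:
    """Rooted tree of 3-D neurite points with cell metadata."""

    nodes: dict[int, SWCNode]
    cell_id: str = ""
    age_group: str = ""
    somatic_depth: float | None = None

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent == -1]
        if len(roots) != 1:
            raise SWCParseError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes.values():
            if n.parent != -1 and n.parent not in self.nodes:
                raise SWCParseError(f"node {n.id} references missing parent {n.parent}")
        # cycle check by walking to the root from every node
        for n in self.nodes.values():
            seen = set()
            cur = n
            while cur.parent != -1:
                if cur.id in seen:
                    raise SWCParseError(f"cycle detected at node {cur.id}")
                seen.add(cur.id)
                cur = self.nodes[cur.parent]

    @property
    def root(self) -> SWCNode:
        return next(n for n in self.nodes.values() if n.parent == -1)

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent != -1:
                ch[n.parent].append(n.id)
        return ch

    def edge_length(self, child_id: int) -> float:
        c = self.nodes[child_id]
        p = self.nodes[c.parent]
        return float(math.dist(c.xyz, p.xyz))


def read_swc(path: str | Path, **metadata) -> MorphologyTree:
    """Parse a standard SWC file; errors name the offending line."""
    nodes: dict[int, SWCNode] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, radius = map(float, parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"{path}:{lineno}: {exc}") from None
        if nid in nodes:
            raise SWCParseError(f"{path}:{lineno}: duplicate node id {nid}")
        nodes[nid] = SWCNode(nid, ntype, x, y, z, radius, parent)
    if not nodes:
        raise SWCParseError(f"{path}: no nodes")
    try:
        return MorphologyTree(nodes, **metadata)
    except SWCParseError as exc:
        raise SWCParseError(f"{path}: {exc}") from None


def write_swc(tree: MorphologyTree, path: str | Path) -> None:
    """Serialize in id order; coordinates printed to 1e-6 µm."""
    lines = ["# id type x y z radius parent"]
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        lines.append(
            f"{n.id} {n.type} {n.x:.6f} {n.y:.6f} {n.z:.6f} {n.radius:.6f} {n.parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# segment decomposition
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    id: int
    start_node: int  # soma or branch point anchoring the segment
    end_node: int  # branch point or terminal
    branch_order: int  # 1 for stems leaving the soma
    path_length: float  # µm, summed inter-node Euclidean distances


@dataclass
class SegmentTable:
    segments: list[Segment]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_length(self) -> float:
        return float(sum(s.path_length for s in self.segments))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment_id": s.id,
                    "start_node": s.start_node,
                    "end_node": s.end_node,
                    "branch_order": s.branch_order,
                    "path_length_um": s.path_length,
                }
                for s in self.segments
            ]
        )


def _included_ids(tree: MorphologyTree, include_axon: bool) -> set[int]:
    keep = set()
    for n in tree.nodes.values():
        if n.type == AXON and not include_axon:
            continue
        keep.add(n.id)
    return keep


def decompose_segments(
    tree: MorphologyTree, include_axon: bool = False
) -> SegmentTable:
    """Split the neurites into maximal unbranched segments.

    Segments are anchored at the soma (the edge from the soma to the
    first neurite node is part of the stem segment), at branch points,
    and end at branch points or terminals.  Zero-length edges are
    collapsed with a warning; they add no length and no nodes.
    """
    keep = _included_ids(tree, include_axon)
    ch_all = tree.children_map()
    ch = {i: [c for c in ch_all[i] if c in keep] for i in keep}
    soma_ids = {n.id for n in tree.nodes.values() if n.type == SOMA}
    if not soma_ids:
        soma_ids = {tree.root.id}

    zero_edges = sum(
        1
        for nid in keep
        if tree.nodes[nid].parent != -1
        and tree.nodes[nid].parent in keep
        and tree.edge_length(nid) == 0.0
    )
    if zero_edges:
        warnings.warn(f"collapsed {zero_edges} zero-length edge(s)")

    segments: list[Segment] = []
    seg_id = 0
    # every neurite child of a soma node or of a branch point starts a segment
    stack: list[tuple[int, int, int]] = []  # (anchor, first_child, order)
    for s in sorted(soma_ids):
        for c in sorted(ch.get(s, [])):
            if c not in soma_ids:
                stack.append((s, c, 1))
    while stack:
        anchor, cur, order = stack.pop()
        length = tree.edge_length(cur)
        prev = cur
        while len(ch[cur]) == 1:
            nxt = ch[cur][0]
            length += tree.edge_length(nxt)
            prev, cur = cur, nxt
        segments.append(
            Segment(
                id=seg_id,
                start_node=anchor,
                end_node=cur,
                branch_order=order,
                path_length=length,
            )
        )
        seg_id += 1
        for c in sorted(ch[cur]):
            stack.append((cur, c, order + 1))
    return SegmentTable(segments)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class MorphoSummary:
    n_segments: int
    total_length: float  # µm
    maximal_length: float  # µm, longest soma-to-tip path
    mean_segment_length: float  # µm
    max_segment_length: float  # µm
    max_branch_order: int
    empty: bool = False


def summarize_morphology(
    tree: MorphologyTree, include_axon: bool = False
) -> MorphoSummary:
    """Morphometric roll-up of one reconstruction."""
    table = decompose_segments(tree, include_axon=include_axon)
    if table.n_segments == 0:
        return MorphoSummary(0, 0.0, 0.0, 0.0, 0.0, 0, empty=True)
    keep = _included_ids(tree, include_axon)
    ch_all = tree.children_map()
    ch = {i: [c for c in ch_all[i] if c in keep] for i in keep}
    # longest root-to-terminal path over included nodes
    root = tree.root
    best = 0.0
    stack = [(root.id, 0.0)]
    while stack:
        nid, dist = stack.pop()
        kids = ch.get(nid, [])
        if not kids:
            best = max(best, dist)
        for c in kids:
            stack.append((c, dist + tree.edge_length(c)))
    lengths = [s.path_length for s in table.segments]
    return MorphoSummary(
        n_segments=table.n_segments,
        total_length=table.total_length,
        maximal_length=best,
        mean_segment_length=float(np.mean(lengths)),
        max_segment_length=float(np.max(lengths)),
        max_branch_order=max(s.branch_order for s in table.segments),
    )


# ---------------------------------------------------------------------------
# depth-feature correlation
# ---------------------------------------------------------------------------

def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho on rank vectors."""
    n = xr.size
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush() -> int:
        perms = np.asarray(chunk, dtype=np.intp)
        r = yc[perms] @ xc / denom
        return int(np.count_nonzero(np.abs(r) >= abs(rho_obs) - 1e-12))

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += flush()
            chunk.clear()
    if chunk:
        count += flush()
    return count / total


def depth_feature_correlation(
    pairs: list[tuple[float, float]], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation of (somatic depth, feature) pairs.

    Exact permutation p for n <= ``exact_max_n``; the large-sample
    approximation above.  Requires at least four complete pairs; a
    constant feature (or constant depth) has no defined correlation.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("pairs must be (depth, feature) tuples")
    if np.any(~np.isfinite(arr)):
        raise DataError("missing values are not allowed")
    n = arr.shape[0]
    if n < 4:
        raise DataError("need at least four paired observations")
    depth, feat = arr[:, 0], arr[:, 1]
    if np.all(depth == depth[0]) or np.all(feat == feat[0]):
        raise DataError("correlation undefined for a constant variable")
    rho, p_approx = stats.spearmanr(depth, feat)
    rho = float(rho)
    if n <= exact_max_n:
        xr = stats.rankdata(depth)
        yr = stats.rankdata(feat)
        return rho, float(_exact_spearman_p(xr, yr, rho))
    return rho, float(p_approx)
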