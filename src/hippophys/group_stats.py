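"""Group summaries and the nonparametric age comparison.

Per-feature group summaries are reported as mean ± sample SD with n,
and every pair of age groups is compared with a two-sided Mann-Whitney
U test at alpha = 0.05.  The U statistic uses midranks for ties.  The
p-value is exact — computed from the full null distribution of rank
assignments — whenever the combined sample is small (n1 + n2 <= 20)
and tie-free, which covers the 5-10 cells per group typical of
patch-clamp studies; otherwise a normal approximation with tie and
continuity corrections is used.  (A cutoff below 16 would silently
push the very group sizes the exact method exists for onto the
anti-conservative approximation.)  No multiplicity adjustment is
applied by default (the Holm step-down procedure is available behind a
flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "GroupSample",
    "MWUResult",
    "GroupSummary",
    "mann_whitney_u",
    "summarize_groups",
    "compare_ages",
]

EXACT_MAX_COMBINED_N = 20
DEFAULT_ALPHA = 0.05


@dataclass
class GroupSample:
    """Non-missing observations of one feature in one group."""

    feature: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        self.values = vals[np.isfinite(vals)]

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class MWUResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    method: str  # "exact" | "normal-approximation"
    tie_corrected: bool


@dataclass
class GroupSummary:
    feature: str
    group: str
    n: int
    mean: float
    sd: float  # NaN when n < 2
    n_missing: int


def _rank_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, bool]:
    """Midranks of the pooled sample and whether any ties occurred."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    tied = False
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        if j > i:
            tied = True
        i = j + 1
    return ranks, tied


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of each U value over all C(n1+n2, n1) equally likely rank splits.

    Dynamic programming over the ranks 1..n: dp[k][s] is the number of
    k-subsets with rank sum s; U = s - k(k+1)/2.
    """
    n = n1 + n2
    max_sum = sum(range(n - n1 + 1, n + 1))
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    base = n1 * (n1 + 1) // 2
    return tuple(int(c) for c in dp[n1, base : base + n1 * n2 + 1])


def _exact_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """Exact two-sided p over the full permutation distribution of U:
    p = P(min(U1, U2) <= min(u_obs, n1*n2 - u_obs))."""
    counts = _u_null_counts(n1, n2)
    u_min = min(u_obs, n1 * n2 - u_obs)
    total = comb(n1 + n2, n1)
    count = sum(
        c for u, c in enumerate(counts)
        if min(u, n1 * n2 - u) <= u_min + 1e-9
    )
    return count / total


def mann_whitney_u(x: GroupSample, y: GroupSample) -> MWUResult:
    """Two-sided Mann-Whitney U test between two group samples."""
    if x.n == 0 or y.n == 0:
        raise DataError("Mann-Whitney requires non-empty groups")
    pooled = np.concatenate([x.values, y.values])
    ranks, tied = _rank_with_ties(pooled)
    n1, n2 = x.n, y.n
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return MWUResult(u=u1, p=1.0, method="exact", tie_corrected=True)

    if n1 + n2 <= EXACT_MAX_COMBINED_N and not tied:
        p = _exact_two_sided_p(u1, n1, n2)
        return MWUResult(u=u1, p=min(p, 1.0), method="exact", tie_corrected=False)

    # normal approximation with tie and continuity corrections
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MWUResult(u=u1, p=1.0, method="normal-approximation", tie_corrected=tied)
    z = (abs(u1 - mu) - 0.5) / sqrt(sigma2)
    z = max(z, 0.0)
    p = erfc(z / sqrt(2.0))
    return MWUResult(u=u1, p=min(p, 1.0), method="normal-approximation", tie_corrected=tied)


def summarize_groups(samples: list[GroupSample], raw_n: dict | None = None) -> pd.DataFrame:
    """Mean ± sample SD (n-1 denominator) and n per (feature, group)."""
    rows = []
    for s in samples:
        if s.n == 0:
            raise DataError(f"empty group {s.group!r} for feature {s.feature!r}")
        rows.append(
            GroupSummary(
                feature=s.feature,
                group=s.group,
                n=s.n,
                mean=float(np.mean(s.values)),
                sd=float(np.std(s.values, ddof=1)) if s.n > 1 else np.nan,
                n_missing=(raw_n or {}).get((s.feature, s.group), s.n) - s.n,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def compare_ages(
    table: pd.DataFrame,
    group_key: str = "age_group",
    features: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    holm: bool = False,
    log: list | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons for every feature in a tidy table.

    ``table`` has one row per cell with a ``group_key`` column and one
    column per feature.  Pairs in which a feature has no observations in
    one group are skipped with a log entry.  The returned report has one
    row per (feature, group pair) with summaries, U, p, and the
    significance flag at ``alpha``.
    """
    if group_key not in table.columns:
        raise DataError(f"missing group column {group_key!r}")
    if features is None:
        features = [
            c for c in table.columns
            if c != group_key and pd.api.types.is_numeric_dtype(table[c])
        ]
    groups = list(dict.fromkeys(table[group_key]))
    if len(groups) < 2:
        raise DataError("need at least two groups to compare")
    rows = []
    for feat in features:
        samples = {
            g: GroupSample(feat, g, table.loc[table[group_key] == g, feat].to_numpy())
            for g in groups
        }
        for g1, g2 in combinations(groups, 2):
            s1, s2 = samples[g1], samples[g2]
            if s1.n == 0 or s2.n == 0:
                if log is not None:
                    log.append(
                        f"skipped {feat}: {g1} vs {g2} (empty group after "
                        "missing-value removal)"
                    )
                continue
            res = mann_whitney_u(s1, s2)
            rows.append(
                {
                    "feature": feat,
                    "group1": g1,
                    "group2": g2,
                    "n1": s1.n,
                    "n2": s2.n,
                    "mean1": float(np.mean(s1.values)),
                    "sd1": float(np.std(s1.values, ddof=1)) if s1.n > 1 else np.nan,
                    "mean2": float(np.mean(s2.values)),
                    "sd2": float(np.std(s2.values, ddof=1)) if s2.n > 1 else np.nan,
                    "U": res.u,
                    "p": res.p,
                    "method": res.method,
                }
            )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if holm:
        report["p_adjusted"] = _holm(report["p"].tolist())
        report["significant"] = report["p_adjusted"] < alpha
    else:
        report["significant"] = report["p"] < alpha
    return report
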