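"""Evolutionary-age comparison of upregulated subfamilies.

RepeatMasker divergence from consensus is the age proxy: lower divergence
means a younger insertion. The question is whether the subfamilies called
"up" in patients are younger than the remaining tested subfamilies, answered
with a two-tailed Mann–Whitney U test on the two divergence samples. Also
provides the cross-tissue intersection of upregulated sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .annotations import SubfamilySummary

__all__ = [
    "AgeComparisonResult",
    "mann_whitney_u",
    "compare_divergence",
    "intersect_upregulated",
    "OverlapResult",
    "EXACT_PAIR_LIMIT",
]

# exact null enumeration up to this many (a, b) pairs; beyond it (or with
# ties) the tie-corrected continuity-corrected normal approximation is used
EXACT_PAIR_LIMIT = 400


@dataclass(frozen=True)
class AgeComparisonResult:
    n_upregulated: int
    n_remainder: int
    median_div_upregulated: float
    median_div_remainder: float
    u_statistic: float
    p_two_sided: float
    direction: str  # 'younger' | 'older' | 'none'

    @property
    def p_defined(self) -> bool:
        return not math.isnan(self.p_two_sided)


@lru_cache(maxsize=64)
def _exact_u_counts(n: int, m: int) -> tuple[float, ...]:
    """Null distribution of U for group sizes (n, m) without ties.

    ``counts[u]`` = number of the C(n+m, n) rank arrangements with statistic
    u; classic recursion c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).
    """
    umax = n * m
    # dp[j][u] for current i; iterate i = 0..n
    prev = [[0.0] * (umax + 1) for _ in range(m + 1)]
    for j in range(m + 1):
        prev[j][0] = 1.0
    for i in range(1, n + 1):
        cur = [[0.0] * (umax + 1) for _ in range(m + 1)]
        cur[0][0] = 1.0
        for j in range(1, m + 1):
            for u in range(umax + 1):
                val = cur[j - 1][u]
                if u >= j:
                    val += prev[j][u - j]
                cur[j][u] = val
        prev = cur
    return tuple(prev[m])


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test; returns ``(U_a, p)``.

    ``U_a`` counts pairs with ``a_i > b_j`` plus half the ties. The exact p is
    computed by enumerating the null rank distribution when ``method='exact'``
    or when ``method='auto'`` with ``n_a * n_b <= EXACT_PAIR_LIMIT`` and no
    ties; otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction is used. Two-sided p = min(1, 2 * smaller tail).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto/exact/normal")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _stats.rankdata(pooled)  # midranks
    r_a = ranks[:n].sum()
    u_a = r_a - n * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    use_exact = method == "exact" or (method == "auto" and n * m <= EXACT_PAIR_LIMIT and not has_ties)
    if use_exact and has_ties:
        raise ValueError("exact method requires tie-free data")
    if use_exact:
        counts = np.asarray(_exact_u_counts(n, m))
        total = counts.sum()
        k = int(round(u_a))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_a), float(p)

    N = n + m
    mu = n * m / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return float(u_a), 1.0  # all values identical
    diff = u_a - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * _stats.norm.sf(abs(z)))
    return float(u_a), float(p)


def compare_divergence(
    de_results: pd.DataFrame,
    summaries: Sequence[SubfamilySummary] | Mapping[str, float],
    alpha: float = 0.05,
    method: str = "auto",
) -> AgeComparisonResult:
    """Mann–Whitney divergence comparison: upregulated vs remaining tested.

    Group A holds the mean divergence of each subfamily with status ``up``;
    group B holds the remaining tested subfamilies (the analysis-eligible
    pool, not the full genomic roster). With no upregulated subfamilies the
    result is flagged (``direction='none'``, NaN p) rather than an error.
    """
    if isinstance(summaries, Mapping):
        div_map = dict(summaries)
    else:
        div_map = {s.subfamily: s.mean_divergence_pct for s in summaries}
    missing = [f for f in de_results["feature_id"] if f not in div_map]
    if missing:
        raise ValueError(f"no divergence for tested subfamilies: {missing[:5]}")
    up_mask = (de_results["status"] == "up").to_numpy()
    feats = de_results["feature_id"].to_numpy()
    div_up = np.array([div_map[f] for f in feats[up_mask]], dtype=float)
    div_rest = np.array([div_map[f] for f in feats[~up_mask]], dtype=float)
    if div_up.size == 0 or div_rest.size == 0:
        return AgeComparisonResult(
            n_upregulated=int(div_up.size),
            n_remainder=int(div_rest.size),
            median_div_upregulated=float(np.median(div_up)) if div_up.size else math.nan,
            median_div_remainder=float(np.median(div_rest)) if div_rest.size else math.nan,
            u_statistic=math.nan,
            p_two_sided=math.nan,
            direction="none",
        )
    u_a, p = mann_whitney_u(div_up, div_rest, method=method)
    med_up = float(np.median(div_up))
    med_rest = float(np.median(div_rest))
    if p < alpha and med_up < med_rest:
        direction = "younger"
    elif p < alpha and med_up > med_rest:
        direction = "older"
    else:
        direction = "none"
    return AgeComparisonResult(
        n_upregulated=int(div_up.size),
        n_remainder=int(div_rest.size),
        median_div_upregulated=med_up,
        median_div_remainder=med_rest,
        u_statistic=float(u_a),
        p_two_sided=float(p),
        direction=direction,
    )


@dataclass
class OverlapResult:
    """Cross-tissue membership of upregulated subfamilies.

    ``membership``: one row per subfamily (lexicographic), one boolean column
    per tissue. ``intersections``: size of every >= 2-way intersection, keyed
    by the sorted tissue tuple.
    """

    membership: pd.DataFrame
    intersections: dict[tuple[str, ...], int]

    def shared_by_all(self) -> list[str]:
        mask = self.membership.all(axis=1)
        return list(self.membership.index[mask])


def intersect_upregulated(
    named_sets: Mapping[str, Sequence[str]] | Sequence[tuple[str, Sequence[str]]],
) -> OverlapResult:
    """Exact set algebra over per-tissue upregulated subfamily sets."""
    if isinstance(named_sets, Mapping):
        pairs = list(named_sets.items())
    else:
        pairs = list(named_sets)
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tissue names")
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {name: set(members) for name, members in pairs}
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [sub in sets[name] for sub in universe] for name in names},
        index=pd.Index(universe, name="subfamily"),
    )
    intersections: dict[tuple[str, ...], int] = {}
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(sorted(names), r):
            common = set.intersection(*(sets[n] for n in combo))
            intersections[combo] = len(common)
    return OverlapResult(membership=membership, intersections=intersections)


def write_age_report(result: AgeComparisonResult, stream: IO[str], comments: Sequence[str] = ()) -> None:
    for c in comments:
        stream.write(f"# {c}\n")
    stream.write(
        "n_upregulated\tn_remainder\tmedian_div_upregulated\tmedian_div_remainder\t"
        "u_statistic\tp_two_sided\tdirection\n"
    )
    stream.write(
        f"{result.n_upregulated}\t{result.n_remainder}\t{result.median_div_upregulated:.6g}\t"
        f"{result.median_div_remainder:.6g}\t{result.u_statistic:.6g}\t"
        f"{result.p_two_sided:.6g}\t{result.direction}\n"
    )


def write_divergence_long_table(
    de_results: pd.DataFrame,
    summaries: Sequence[SubfamilySummary] | Mapping[str, float],
    stream: IO[str],
) -> None:
    """Box-plot-ready long format: subfamily, group (up/remainder), divergence."""
    if isinstance(summaries, Mapping):
        div_map = dict(summaries)
    else:
        div_map = {s.subfamily: s.mean_divergence_pct for s in summaries}
    stream.write("subfamily\tgroup\tdivergence_pct\n")
    for _, row in de_results.iterrows():
        group = "upregulated" if row["status"] == "up" else "remainder"
        stream.write(f"{row['feature_id']}\t{group}\t{div_map[row['feature_id']]:.6g}\n")
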