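"""Differential expression between conditions.

Per-feature Welch t-tests (unequal-variance two-sample t with
Welch–Satterthwaite degrees of freedom) on FPKM values, Holm step-down
family-wise adjustment across the tested features, and volcano-style calls:
a subfamily is "up" when the Holm-adjusted p is below alpha AND the
pseudocounted fold-change exceeds the fold-change threshold.

The severity contrast (non-ICU vs ICU patients) reuses the same statistics
without multiplicity adjustment by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .quantification import ExpressionMatrix

__all__ = [
    "DEThresholds",
    "welch_t_test",
    "welch_t_test_matrix",
    "holm_adjust",
    "call_differential",
    "severity_comparison",
    "DE_COLUMNS",
]

DE_COLUMNS = [
    "feature_id",
    "mean_fpkm_control",
    "mean_fpkm_case",
    "log2fc",
    "t_stat",
    "df_welch",
    "p_value",
    "p_adjusted",
    "status",
]


@dataclass(frozen=True)
class DEThresholds:
    """Calling thresholds: Holm-adjusted p < alpha and fold-change > min_fold_change.

    The pseudocount (in FPKM units) enters fold-changes only, never the
    t-test, and keeps log2 fold-changes finite at zero means.
    """

    alpha: float = 0.05
    min_fold_change: float = 2.0
    pseudocount_fpkm: float = 0.01
    adjust: str = "holm"
    log_transform: bool = False  # test log2(FPKM + pseudocount) instead of raw FPKM

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold_change <= 1.0:
            raise ValueError("min_fold_change must be > 1")
        if self.pseudocount_fpkm <= 0.0:
            raise ValueError("pseudocount must be > 0")
        if self.adjust not in ("holm", "none"):
            raise ValueError("adjust must be 'holm' or 'none'")


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with ``t = (mean_x - mean_y) / sqrt(s2_x/n_x +
    s2_y/n_y)`` (unbiased variances), Welch–Satterthwaite degrees of freedom,
    and the two-sided Student-t tail probability. Both groups need >= 2 finite
    values. When both groups have zero variance and equal means the test is
    degenerate and reports ``t = 0, p = 1``; zero variance with unequal means
    reports an infinite t and ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    t, df, p = welch_t_test_matrix(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def welch_t_test_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t-test: ``X`` is features x n_x, ``Y`` features x n_y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    nx, ny = X.shape[1], Y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    degenerate = se2 == 0.0
    equal = degenerate & (diff == 0.0)
    unequal = degenerate & (diff != 0.0)
    t = np.where(equal, 0.0, t)
    t = np.where(unequal, np.where(diff > 0, np.inf, -np.inf), t)
    df = np.where(degenerate, np.nan, df)
    p = np.empty_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * _stats.t.sf(np.abs(t[ok]), df[ok])
    p[equal] = 1.0
    p[unequal] = 0.0
    return t, df, p


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending; ``adj(i) = min(1, max_{j<=i} (m - j + 1) * p_(j))`` with a
    stable sort so ties keep their input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _split_by_condition(
    fpkm: ExpressionMatrix | pd.DataFrame,
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    df = fpkm.values if isinstance(fpkm, ExpressionMatrix) else fpkm
    a = [s for s in df.columns if labels.get(s) == group_a]
    b = [s for s in df.columns if labels.get(s) == group_b]
    return df, a, b


def _de_table(
    df: pd.DataFrame,
    control_cols: Sequence[str],
    case_cols: Sequence[str],
    thresholds: DEThresholds,
) -> pd.DataFrame:
    eps = thresholds.pseudocount_fpkm
    # all-zero features in both groups carry no signal; exclude before testing
    sub = df[list(control_cols) + list(case_cols)]
    tested_mask = (sub.to_numpy() != 0).any(axis=1)
    tested = df.loc[tested_mask]
    excluded = df.index[~tested_mask]

    ctrl = tested[list(control_cols)].to_numpy(dtype=float)
    case = tested[list(case_cols)].to_numpy(dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_case = case.mean(axis=1)
    if thresholds.log_transform:
        t, dfree, p = welch_t_test_matrix(np.log2(case + eps), np.log2(ctrl + eps))
    else:
        t, dfree, p = welch_t_test_matrix(case, ctrl)
    if thresholds.adjust == "holm":
        p_adj = holm_adjust(p)
    else:
        p_adj = p.copy()
    ratio = (mean_case + eps) / (mean_ctrl + eps)
    log2fc = np.log2(ratio)
    status = np.full(tested.shape[0], "ns", dtype=object)
    sig = p_adj < thresholds.alpha
    status[sig & (ratio > thresholds.min_fold_change)] = "up"
    status[sig & (ratio < 1.0 / thresholds.min_fold_change)] = "down"
    table = pd.DataFrame(
        {
            "feature_id": tested.index,
            "mean_fpkm_control": mean_ctrl,
            "mean_fpkm_case": mean_case,
            "log2fc": log2fc,
            "t_stat": t,
            "df_welch": dfree,
            "p_value": p,
            "p_adjusted": p_adj,
            "status": status,
        }
    ).reset_index(drop=True)
    table.attrs["excluded_all_zero"] = list(excluded)
    return table


def call_differential(
    fpkm: ExpressionMatrix | pd.DataFrame,
    conditions: Mapping[str, str],
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Case-vs-control differential table for every tested feature.

    ``conditions`` maps sample id to ``'control'``/``'covid'``. Features with
    all-zero values in both groups are excluded before testing (listed in
    ``table.attrs['excluded_all_zero']``); the Holm family is the set of
    tested features of this run. Returns a DataFrame with :data:`DE_COLUMNS`.
    """
    df, ctrl_cols, case_cols = _split_by_condition(fpkm, conditions, "control", "covid")
    if len(ctrl_cols) < 2 or len(case_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per condition (control={len(ctrl_cols)}, covid={len(case_cols)})"
        )
    return _de_table(df, ctrl_cols, case_cols, thresholds)


def severity_comparison(
    fpkm: ExpressionMatrix | pd.DataFrame,
    severities: Mapping[str, str],
    features: Sequence[str] | None = None,
    thresholds: DEThresholds | None = None,
) -> pd.DataFrame:
    """ICU vs non-ICU contrast among patients, unadjusted by default.

    ``severities`` maps sample id to ``non_icu``/``icu`` (others are treated
    as descriptive bystanders: samples labelled neither way contribute a
    ``mean_fpkm_other`` column, e.g. healthy controls). "Case" is the ICU
    group, so positive log2fc means higher in severe disease.
    """
    if thresholds is None:
        thresholds = DEThresholds(adjust="none")
    df = fpkm.values if isinstance(fpkm, ExpressionMatrix) else fpkm
    if features is not None:
        df = df.loc[list(features)]
    non_icu = [s for s in df.columns if severities.get(s) == "non_icu"]
    icu = [s for s in df.columns if severities.get(s) == "icu"]
    other = [s for s in df.columns if s not in non_icu and s not in icu]
    if len(non_icu) < 2 or len(icu) < 2:
        raise ValueError(
            f"need >= 2 samples per severity group (non_icu={len(non_icu)}, icu={len(icu)})"
        )
    table = _de_table(df, control_cols=non_icu, case_cols=icu, thresholds=thresholds)
    table = table.rename(
        columns={"mean_fpkm_control": "mean_fpkm_non_icu", "mean_fpkm_case": "mean_fpkm_icu"}
    )
    if other:
        other_means = df[other].mean(axis=1)
        table["mean_fpkm_other"] = table["feature_id"].map(other_means)
    return table


def write_de_table(table: pd.DataFrame, stream: IO[str], comments: Sequence[str] = ()) -> None:
    for c in comments:
        stream.write(f"# {c}\n")
    table.to_csv(stream, sep="\t", index=False)


def read_de_table(path_or_stream) -> pd.DataFrame:
    return pd.read_csv(path_or_stream, sep="\t", comment="#")
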