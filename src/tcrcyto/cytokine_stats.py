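"""Cytokine panel preprocessing and group comparison.

The preprocessing chain mirrors the multiplex-panel analysis convention for
small clinical cohorts and is applied in a fixed order:

1. IQR outlier screen within each (analyte, group): a value is an outlier if
   it lies below Q1 - k*IQR or above Q3 + k*IQR (default k = 2); a sample
   flagged for at least ``sample_flag_fraction`` of its evaluable analytes is
   removed outright.
2. ``log2(x + 1)`` variance-stabilising transform.
3. Winsorization at 12.5 % per tail, clamping to the tail quantiles.

All quantiles use linear interpolation between order statistics (R type-7 /
numpy default), shared by the outlier screen and the Winsorizer.
Not-detected cells (NaN) are excluded from quantiles, tests and means and
stay masked through every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CytokinePanel


@dataclass
class OutlierReport:
    """Per-(analyte, group) quartile bounds and the samples they flag."""

    bounds: pd.DataFrame          # analyte, group, q1, q3, iqr, lower, upper
    flags: pd.DataFrame           # samples x analytes boolean
    flag_fraction: pd.Series      # per sample: flagged / evaluable analytes
    removed_samples: list[str]
    skipped: list[tuple[str, str]]  # (analyte, group) with <4 detected values


@dataclass
class GroupComparison:
    """Per-analyte two-group test with BH-adjusted significance."""

    table: pd.DataFrame           # analyte-indexed: fold_change, statistic, raw_p, adjusted_p, significant
    test: str
    alpha: float
    skipped: list[str] = field(default_factory=list)


def _quantile(values: np.ndarray, q) -> np.ndarray:
    """Linear-interpolation quantile, the convention shared package-wide."""
    return np.quantile(values, q, method="linear")


def detect_outliers(
    panel: CytokinePanel,
    groups: pd.Series,
    k: float = 2.0,
    sample_flag_fraction: float = 0.25,
) -> OutlierReport:
    """IQR outlier screen within each (analyte, group).

    ``groups`` maps sample id -> group label.  Analyte/group cells with fewer
    than four detected values cannot support quartiles and are skipped with a
    warning.  Strict inequalities: with IQR = 0 the bounds collapse onto the
    quartiles and nothing is flagged.
    """
    groups = groups.reindex(panel.values.index)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    if groups.groupby(groups).size().eq(0).any() or len(groups) == 0:
        raise ValueError("empty group")

    flags = pd.DataFrame(False, index=panel.values.index, columns=panel.values.columns)
    evaluable = pd.DataFrame(False, index=panel.values.index, columns=panel.values.columns)
    bounds_rows = []
    skipped: list[tuple[str, str]] = []
    for group, members in groups.groupby(groups).groups.items():
        sub = panel.values.loc[list(members)]
        for analyte in sub.columns:
            col = sub[analyte].dropna()
            if len(col) < 4:
                skipped.append((analyte, str(group)))
                continue
            q1, q3 = _quantile(col.to_numpy(), [0.25, 0.75])
            iqr = q3 - q1
            lower, upper = q1 - k * iqr, q3 + k * iqr
            bounds_rows.append(
                {"analyte": analyte, "group": group, "q1": q1, "q3": q3,
                 "iqr": iqr, "lower": lower, "upper": upper}
            )
            flagged = (col < lower) | (col > upper)
            flags.loc[flagged.index[flagged], analyte] = True
            evaluable.loc[col.index, analyte] = True

    n_eval = evaluable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = flags.sum(axis=1) / n_eval.replace(0, np.nan)
    frac = frac.fillna(0.0)
    removed = list(frac.index[frac >= sample_flag_fraction])
    if skipped:
        warnings.warn(
            f"outlier screen skipped {len(skipped)} (analyte, group) cells with <4 detected values"
        )
    bounds = pd.DataFrame(
        bounds_rows, columns=["analyte", "group", "q1", "q3", "iqr", "lower", "upper"]
    )
    return OutlierReport(bounds, flags, frac, removed, skipped)


def log2p1(values):
    """Elementwise log2(x + 1); NaN (not detected) passes through."""
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("log2p1 requires non-negative values")
    out = np.log2(arr + 1.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def winsorize(values, tail_prob: float = 0.125):
    """Clamp a 1-D vector to its [tail_prob, 1 - tail_prob] quantiles.

    NaN entries are ignored when computing the quantiles and preserved in the
    output.  Idempotent: re-winsorizing clamped data changes nothing, because
    the clamped tails sit exactly at the old tail quantiles.
    """
    if not 0 <= tail_prob < 0.5:
        raise ValueError(f"tail_prob must be in [0, 0.5), got {tail_prob}")
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise ValueError("winsorize needs at least two finite values")
    lo, hi = _quantile(finite, [tail_prob, 1.0 - tail_prob])
    out = np.clip(arr, lo, hi)
    out[np.isnan(arr)] = np.nan
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def winsorize_columns(matrix: pd.DataFrame, tail_prob: float = 0.125) -> pd.DataFrame:
    """Winsorize each column (analyte) of a samples x analytes matrix."""
    out = {}
    for col in matrix.columns:
        vals = matrix[col]
        if vals.notna().sum() < 2:
            out[col] = vals
        else:
            out[col] = winsorize(vals, tail_prob)
    return pd.DataFrame(out, index=matrix.index)[matrix.columns]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0 / sample sd 1 (ddof = 1), mask-aware.

    Zero-variance rows become all zeros with a warning rather than an error,
    so a constant analyte still renders as a flat heatmap row.
    """
    out = matrix.copy().astype(float)
    flat_rows = []
    for idx in matrix.index:
        row = matrix.loc[idx]
        obs = row.dropna()
        if len(obs) < 2:
            raise ValueError(f"row {idx!r} has <2 detected values")
        sd = obs.std(ddof=1)
        if sd == 0:
            out.loc[idx] = np.where(row.isna(), np.nan, 0.0)
            flat_rows.append(idx)
        else:
            out.loc[idx] = (row - obs.mean()) / sd
    if flat_rows:
        warnings.warn(f"zero-variance rows set to 0: {flat_rows}")
    return out


def preprocess_panel(
    panel: CytokinePanel,
    groups: pd.Series,
    outlier_k: float = 2.0,
    sample_flag_fraction: float = 0.25,
    winsor_tail: float = 0.125,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Fixed-order preprocessing: outlier removal -> log2(x+1) -> Winsorize.

    Returns the processed samples x analytes matrix (outlier samples dropped)
    and the outlier report.
    """
    report = detect_outliers(panel, groups, k=outlier_k,
                             sample_flag_fraction=sample_flag_fraction)
    kept = [s for s in panel.values.index if s not in set(report.removed_samples)]
    logged = log2p1(panel.values.loc[kept])
    return winsorize_columns(logged, winsor_tail), report


def linkage_order(matrix: pd.DataFrame) -> list:
    """Row order from complete-linkage hierarchical clustering (Euclidean).

    Heatmap export helper: returns the dendrogram leaf order of the rows.
    Missing cells are filled with the row mean (i.e. 0 after z-scoring) for
    the distance computation only.
    """
    from scipy.cluster.hierarchy import complete, leaves_list

    filled = matrix.apply(lambda row: row.fillna(row.mean()), axis=1)
    if len(filled) < 2:
        return list(matrix.index)
    order = leaves_list(complete(filled.to_numpy()))
    return [matrix.index[i] for i in order]


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, otherwise
    normal approximation with tie and continuity correction."""
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and max(len(x), len(y)) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    panel: CytokinePanel,
    groups: pd.Series,
    group_a: str = "MS",
    group_b: str = "CTRL",
    test: str = "mann_whitney",
    alpha: float = 0.05,
) -> GroupComparison:
    """Per-analyte two-group comparison with BH adjustment across analytes.

    Fold change is the ratio of raw-scale group means (group_a / group_b);
    the median-based ratio is reported alongside.  Analytes with fewer than
    two detected values in either group are skipped and recorded.
    """
    from .correlation_network import bh_adjust

    groups = groups.reindex(panel.values.index)
    a_ids = groups.index[groups == group_a]
    b_ids = groups.index[groups == group_b]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError(f"empty group: {group_a}={len(a_ids)}, {group_b}={len(b_ids)}")

    rows, skipped = [], []
    for analyte in panel.values.columns:
        x = panel.values.loc[a_ids, analyte].dropna().to_numpy()
        y = panel.values.loc[b_ids, analyte].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            skipped.append(analyte)
            continue
        if test == "mann_whitney":
            stat, p = _mann_whitney(x, y)
        elif test == "welch_t":
            res = stats.ttest_ind(x, y, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        my = y.mean()
        rows.append(
            {
                "analyte": analyte,
                "fold_change": x.mean() / my if my > 0 else np.inf,
                "fold_change_median": (np.median(x) / np.median(y)
                                       if np.median(y) > 0 else np.inf),
                "statistic": stat,
                "raw_p": p,
                "n_a": len(x),
                "n_b": len(y),
            }
        )
    table = pd.DataFrame(rows).set_index("analyte") if rows else pd.DataFrame(
        columns=["fold_change", "fold_change_median", "statistic", "raw_p", "n_a", "n_b"]
    )
    if len(table):
        table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        table["significant"] = table["adjusted_p"] < alpha
    return GroupComparison(table, test, alpha, skipped)
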