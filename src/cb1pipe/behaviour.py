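"""Symptom time-course statistics for the drug/placebo crossover.

Ratings are taken immediately before and at 1, 2 and 3 hours after drug
administration.  The summary measures are the trapezoidal area under the
effect-time curve, the non-parametric Friedman test across conditions
(chosen because placebo ratings carry no variance and drug responses are
right-skewed), a Kolmogorov-Smirnov normality check of the change from
baseline, and the 1-2 h window mean used for correlational analyses.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc_trapezoid",
    "friedman_chi2",
    "ks_normality",
    "window_mean_1_2h",
    "analyse_ratings",
]


def auc_trapezoid(times_h, values) -> float:
    """Trapezoidal area under the curve, in rating-scale x hours units."""
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def _chi2_from_ranks(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1)) over tied groups
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts.astype(float) ** 3 - counts)
    denom = 1.0 - ties / (n * k * (k * k - 1.0))
    if denom <= 0:
        return 0.0  # all values tied within every subject
    return float(chi2 / denom)


def friedman_chi2(paired_matrix, method: str = "asymptotic"):
    """Friedman test across k paired conditions.

    Parameters
    ----------
    paired_matrix : (n_subjects, k_conditions) array
        Complete data, no missing cells.
    method : {"asymptotic", "exact"}
        "exact" enumerates all within-subject rank permutations (k!^n
        arrangements) and returns the permutation p-value of the
        tie-corrected statistic; feasible for small n and k only.

    Returns
    -------
    (chi2, df, p)
    """
    x = np.asarray(paired_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    ranks = _rank_matrix(x)
    chi2 = _chi2_from_ranks(ranks)
    df = k - 1
    if method == "asymptotic":
        p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    elif method == "exact":
        perms = list(permutations(range(k)))
        if len(perms) ** n > 2_000_000:
            raise ValueError("exact enumeration infeasible for this n, k")
        count = 0
        total = 0
        base_rows = [ranks[i] for i in range(n)]
        for combo in product(range(len(perms)), repeat=n):
            arranged = np.array([base_rows[i][list(perms[c])]
                                 for i, c in enumerate(combo)])
            total += 1
            if _chi2_from_ranks(arranged) >= chi2 - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(chi2), df, float(p)


def ks_normality(changes_from_baseline):
    """One-sample KS test against a normal with the sample mean and SD.

    Returns (D, p) with the asymptotic p-value.  Raises on zero-variance
    samples, for which the reference distribution is degenerate.
    """
    x = np.asarray(changes_from_baseline, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def window_mean_1_2h(series) -> float:
    """Mean of the 1 h and 2 h ratings (the fMRI acquisition window).

    ``series`` maps time in hours to value (dict, Series, or pair of
    arrays); both the 1 h and 2 h timepoints must be present.
    """
    if isinstance(series, pd.Series):
        mapping = {float(k): float(v) for k, v in series.items()}
    elif isinstance(series, dict):
        mapping = {float(k): float(v) for k, v in series.items()}
    else:
        t, v = series
        mapping = {float(a): float(b) for a, b in zip(t, v)}
    try:
        return (mapping[1.0] + mapping[2.0]) / 2.0
    except KeyError as exc:
        raise ValueError("1 h and 2 h timepoints required") from exc


def analyse_ratings(table: pd.DataFrame, friedman_on: str = "auc",
                    baseline_subtract_auc: bool = False,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Per-scale summary statistics for a long-format ratings table.

    For each scale: per-condition mean AUC (trapezoidal, raw ratings by
    default), the Friedman chi-square across conditions computed on the
    per-subject AUCs (``friedman_on="auc"``) or stacked per-timepoint
    values, and the KS normality check of the drug-placebo change from
    baseline at the 1-2 h window.
    """
    required = {"subject", "condition", "scale", "time_h", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"ratings table must have columns {sorted(required)}")
    out = []
    n_scales = table["scale"].nunique()
    for scale, sub in table.groupby("scale", sort=True):
        wide = sub.pivot_table(index=["subject", "condition"], columns="time_h",
                               values="value")
        times = np.asarray(sorted(wide.columns), dtype=float)
        aucs = {}
        windows = {}
        for cond in sub["condition"].unique():
            block = wide.xs(cond, level="condition").sort_index()
            vals = block[sorted(block.columns)].to_numpy()
            if baseline_subtract_auc:
                vals = vals - vals[:, :1]
            aucs[cond] = np.array([auc_trapezoid(times, row) for row in vals])
            windows[cond] = block[1.0].to_numpy() / 2.0 + block[2.0].to_numpy() / 2.0
        conds = sorted(aucs)
        if friedman_on == "auc":
            mat = np.column_stack([aucs[c] for c in conds])
        elif friedman_on == "timepoints":
            mat = np.vstack([
                np.column_stack([wide.xs(c, level="condition").sort_index()[t]
                                 for c in conds])
                for t in times if t > 0])
        else:
            raise ValueError("friedman_on must be 'auc' or 'timepoints'")
        chi2, df, p = friedman_chi2(mat)
        if bonferroni:
            p = min(1.0, p * n_scales)
        if "drug" in windows and "placebo" in windows:
            delta = windows["drug"] - windows["placebo"]
        else:
            delta = windows[conds[-1]] - windows[conds[0]]
        try:
            ks_d, ks_p = ks_normality(delta)
        except ValueError:
            ks_d, ks_p = np.nan, np.nan
        row = {"scale": scale, "friedman_chi2": chi2, "df": df, "p": p,
               "ks_D": ks_d, "ks_p": ks_p,
               "mean_window_delta": float(np.mean(delta))}
        for c in conds:
            row[f"auc_{c}"] = float(np.mean(aucs[c]))
        out.append(row)
    return pd.DataFrame(out)
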