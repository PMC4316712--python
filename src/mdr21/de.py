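"""Differential expression for gene and miRNA matrices.

Implements the three statistical blocks the integration stage needs:

* quantile normalization — every sample column receives the identical sorted
  value vector (the cross-column rank means), the standard device for making
  intensity distributions comparable before testing;
* a per-feature two-group test (Welch's t by default, pooled-variance t on
  request) with Benjamini-Hochberg FDR control;
* a SAM-style analysis: moderated d statistic d = (mean_t - mean_n)/(s + s0)
  with the pooled standard error s and a fudge constant s0 (default: the
  median of all s), plus a label-permutation FDR (median count of permuted
  |d*| exceedances over observed exceedances, monotonized).

"Downregulated" throughout means effect < 0 and q below a cutoff
(default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "quantile_normalize",
    "welch_t_test",
    "bh_fdr",
    "sam_statistic",
    "sam_permutation_fdr",
    "downregulated",
]


@dataclass
class ExpressionDataset:
    """features x samples log-scale expression with tumor/normal labels."""

    values: np.ndarray
    feature_ids: list[str]
    groups: np.ndarray  # 'tumor' / 'normal' per sample
    label: str = ""
    annotation: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != (len(self.feature_ids), len(self.groups)):
            raise ValueError("values must be features x samples")
        for g in ("tumor", "normal"):
            if int(np.sum(self.groups == g)) < 2:
                raise ValueError(f"need >= 2 {g} samples")
        if np.isnan(self.values).all(axis=1).any():
            raise ValueError("all-missing feature row")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.values[:, self.groups == "tumor"],
                self.values[:, self.groups == "normal"])


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force identical value distributions across columns.

    Each column's rank r receives the mean across columns of the r-th
    smallest values; ties within a column get the mean of their rank means.
    Missing cells are rank-skipped: a column's non-missing values are mapped
    onto the reference distribution by interpolation on the quantile scale,
    and NaNs stay NaN. A single column is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("need a 2-D matrix")
    n_rows, n_cols = matrix.shape
    if n_cols < 2:
        import warnings

        warnings.warn("quantile normalization of a single column is a no-op")
        return matrix.copy()
    if not np.isnan(matrix).any():
        ref = np.sort(matrix, axis=0).mean(axis=1)
        out = np.empty_like(matrix)
        for j in range(n_cols):
            col = matrix[:, j]
            order = np.argsort(col, kind="mergesort")
            ranked = np.empty(n_rows)
            ranked[order] = ref
            # ties: average the rank means over each tied block
            for val, idx in _tied_groups(col):
                ranked[idx] = ranked[idx].mean()
            out[:, j] = ranked
        return out
    # missing-aware path: interpolate each column onto the reference quantiles
    ref_q = np.linspace(0, 1, n_rows)
    col_sorted = [np.sort(matrix[~np.isnan(matrix[:, j]), j]) for j in range(n_cols)]
    ref = np.mean(
        [np.interp(ref_q, np.linspace(0, 1, len(c)), c) for c in col_sorted],
        axis=0,
    )
    out = np.full_like(matrix, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(matrix[:, j])
        col = matrix[mask, j]
        m = len(col)
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(m)
        ranked[order] = np.interp(np.linspace(0, 1, m), ref_q, ref)
        for val, idx in _tied_groups(col):
            ranked[idx] = ranked[idx].mean()
        out[mask, j] = ranked
    return out


def _tied_groups(col: np.ndarray):
    vals, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
    for v in np.flatnonzero(counts > 1):
        yield vals[v], inv == v


def welch_t_test(dataset: ExpressionDataset, equal_var: bool = False) -> pd.DataFrame:
    """Per-feature two-sided two-sample t test (Welch by default).

    Returns a frame with effect = mean(tumor) - mean(normal), t, p and
    BH-adjusted q. Degenerate rows (zero variance in both groups) get t = 0,
    p = 1 when the means agree, else p = 0 with flag = 'degenerate'.
    """
    import warnings

    tum, nor = dataset.split()
    with warnings.catch_warnings():
        # constant rows trigger scipy's catastrophic-cancellation warning;
        # those rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(tum, nor, axis=1, equal_var=equal_var,
                              nan_policy="omit")
    effect = np.nanmean(tum, axis=1) - np.nanmean(nor, axis=1)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    flag = np.full(len(effect), "", dtype=object)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = degenerate & (np.abs(effect) < 1e-12)
        diff = degenerate & ~same
        t[same], p[same] = 0.0, 1.0
        t[diff] = np.sign(effect[diff]) * np.inf
        p[diff] = 0.0
        flag[diff] = "degenerate"
    frame = pd.DataFrame(
        {
            "feature_id": dataset.feature_ids,
            "effect": effect,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "flag": flag,
        }
    )
    frame.attrs["dataset"] = dataset.label
    return frame


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sam_statistic(
    dataset: ExpressionDataset, s0_quantile: float = 0.5
) -> tuple[pd.DataFrame, float]:
    """SAM moderated statistic d = (mean_t - mean_n) / (s + s0).

    s is the pooled standard error
    sqrt((1/n_t + 1/n_n) * (SS_t + SS_n) / (n_t + n_n - 2)) and s0 is the
    ``s0_quantile`` of all s values (the full SAM s0 optimization grid is
    intentionally not reproduced). If every s is zero, s0 falls back to a
    machine-epsilon scale and the result is flagged.
    """
    tum, nor = dataset.split()
    frame, s0 = _sam_frame(tum, nor, dataset.feature_ids, s0_quantile)
    frame.attrs["dataset"] = dataset.label
    return frame, s0


def _sam_d(tum: np.ndarray, nor: np.ndarray, s0: float | None,
           s0_quantile: float) -> tuple[np.ndarray, np.ndarray, float]:
    nt, nn = tum.shape[1], nor.shape[1]
    effect = tum.mean(axis=1) - nor.mean(axis=1)
    ss = ((tum - tum.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (nor - nor.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / nt + 1.0 / nn) * ss / (nt + nn - 2))
    if s0 is None:
        s0 = float(np.quantile(s, s0_quantile))
        if s0 == 0.0 and np.all(s == 0.0):
            s0 = float(np.finfo(float).eps)
    d = effect / (s + s0)
    return d, s, s0


def _sam_frame(tum, nor, feature_ids, s0_quantile):
    d, s, s0 = _sam_d(tum, nor, None, s0_quantile)
    flagged = s0 <= np.finfo(float).eps and np.all(s == 0.0)
    frame = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "effect": tum.mean(axis=1) - nor.mean(axis=1),
            "d": d,
            "s": s,
            "flag": "all-s-zero" if flagged else "",
        }
    )
    frame.attrs["s0"] = s0
    return frame, s0


def sam_permutation_fdr(
    dataset: ExpressionDataset,
    n_perm: int = 500,
    seed: int = 0,
    s0_quantile: float = 0.5,
) -> pd.DataFrame:
    """SAM analysis with label-permutation FDR.

    For each observed |d| threshold t, FDR(t) = median over permutations of
    #{|d*| >= t} divided by #{|d| >= t}, monotonized to be non-increasing in
    t and capped at 1; each feature's q is the FDR at its own |d|. s0 is
    computed once from the observed grouping and reused for permutations.
    When the number of distinct label assignments is at most n_perm, all of
    them are enumerated instead of sampling.
    """
    tum, nor = dataset.split()
    nt, nn = tum.shape[1], nor.shape[1]
    all_vals = np.concatenate([tum, nor], axis=1)
    n = nt + nn
    d_obs, s, s0 = _sam_d(tum, nor, None, s0_quantile)
    abs_obs = np.abs(d_obs)

    n_distinct = comb(n, nt)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        from itertools import combinations

        assignments = [np.array(c) for c in combinations(range(n), nt)]
    else:
        assignments = [rng.permutation(n)[:nt] for _ in range(n_perm)]

    order = np.argsort(abs_obs)  # ascending |d|
    sorted_abs = abs_obs[order]
    # observed exceedance count at each feature's own threshold
    n_obs_ge = len(abs_obs) - np.arange(len(abs_obs))
    counts = np.empty((len(assignments), len(abs_obs)))
    idx_all = np.arange(n)
    for r, tum_idx in enumerate(assignments):
        mask = np.zeros(n, dtype=bool)
        mask[tum_idx] = True
        d_perm, _, _ = _sam_d(all_vals[:, mask], all_vals[:, ~mask], s0, s0_quantile)
        # permuted |d*| exceeding each observed threshold
        perm_sorted = np.sort(np.abs(d_perm))
        counts[r] = len(perm_sorted) - np.searchsorted(
            perm_sorted, sorted_abs, side="left"
        )
    med = np.median(counts, axis=0)
    fdr_sorted = med / n_obs_ge
    # q of a feature = min FDR over thresholds that keep it in the rejection
    # set (its own |d| or lower): prefix-min in ascending |d| order, which
    # also makes q non-increasing in |d|
    fdr_sorted = np.minimum.accumulate(fdr_sorted)
    np.clip(fdr_sorted, 0.0, 1.0, out=fdr_sorted)
    q = np.empty_like(fdr_sorted)
    q[order] = fdr_sorted
    frame = pd.DataFrame(
        {
            "feature_id": dataset.feature_ids,
            "effect": tum.mean(axis=1) - nor.mean(axis=1),
            "d": d_obs,
            "s": s,
            "q": q,
        }
    )
    frame.attrs["s0"] = s0
    frame.attrs["dataset"] = dataset.label
    return frame


def downregulated(result: pd.DataFrame, q_cut: float = 0.05) -> set[str]:
    """Features with negative effect and q below the cutoff."""
    mask = (result["effect"] < 0) & (result["q"] < q_cut)
    return set(result.loc[mask, "feature_id"])
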