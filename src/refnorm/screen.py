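"""Stable reference-gene screening from a normalized expression matrix.

Implements the candidate-selection cascade used to mine time-course
microarray data for normalization references:

1. per-day log2 fold changes against the baseline day;
2. differential-expression calls (any-day fold change plus a per-gene
   one-way ANOVA F test across days with Benjamini-Hochberg adjustment,
   or user-supplied p-values);
3. the "typical expression" window, taken from the A_mean (per-gene mean
   normalized intensity) of the differentially expressed genes;
4. the stability screen proper: less than a given percent expression
   change at every day, A_mean inside the window, and a low coefficient
   of variation across individual hybridizations (CV_A).

The :class:`StableGeneScreen` estimator wraps the cascade in the
scikit-learn fit/transform idiom (arrays as rows, genes as columns); the
module functions operate on the genes-by-arrays orientation used by the
CSV files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, DomainError

__all__ = [
    "compute_fold_changes",
    "anova_pvalues",
    "select_de_genes",
    "typical_expression_range",
    "screen_stable_genes",
    "StableGeneScreen",
]


def _check_design(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    design = design.copy()
    for col in ("sample", "day"):
        if col not in design.columns:
            raise DesignError(f"design table lacks a '{col}' column")
    missing = set(values.columns) - set(design["sample"])
    if missing:
        raise DesignError(f"arrays absent from design: {sorted(missing)[:5]}")
    if design["sample"].duplicated().any():
        raise DesignError("design maps one array to several (day, replicate) rows")
    return design[design["sample"].isin(values.columns)]


def _day_order(design: pd.DataFrame) -> list:
    # day labels are opaque; order = first appearance in the design file
    return list(dict.fromkeys(design["day"]))


def compute_fold_changes(values: pd.DataFrame, design: pd.DataFrame,
                         baseline_day=None) -> pd.DataFrame:
    """Per-gene, per-day log2 fold change versus the baseline day.

    ``log2FC(g, d)`` is the mean log2 intensity of gene *g* over the
    arrays of day *d* minus the mean over baseline arrays. Columns are
    the non-baseline days in design order.
    """
    design = _check_design(values, design)
    days = _day_order(design)
    if baseline_day is None:
        baseline_day = days[0]
    if baseline_day not in days:
        raise DesignError(f"baseline day {baseline_day!r} not in design")
    day_means = {
        d: values[design.loc[design["day"] == d, "sample"]].mean(axis=1)
        for d in days
    }
    base = day_means[baseline_day]
    out = {d: day_means[d] - base for d in days if d != baseline_day}
    return pd.DataFrame(out)


def anova_pvalues(values: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Ordinary one-way ANOVA F-test p-value per gene, across day groups."""
    design = _check_design(values, design)
    days = _day_order(design)
    groups = [values[design.loc[design["day"] == d, "sample"]].to_numpy()
              for d in days]
    n_total = sum(g.shape[1] for g in groups)
    if len(groups) < 2 or n_total - len(groups) < 1:
        raise DesignError(
            "ANOVA requires >=2 day groups and residual degrees of freedom; "
            "supply external p-values for single-replicate designs"
        )
    stat = stats.f_oneway(*groups, axis=1)
    return pd.Series(stat.pvalue, index=values.index, name="pvalue")


def adjust_pvalues(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg FDR adjustment."""
    adj = multipletests(pvalues.to_numpy(), method="fdr_bh")[1]
    return pd.Series(adj, index=pvalues.index, name="adj_pvalue")


def select_de_genes(
    fold_changes: pd.DataFrame,
    adj_pvalues: pd.Series,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.0005,
    early_day=None,
    late_day=None,
) -> pd.DataFrame:
    """Flag differentially expressed and progressively changing genes.

    ``is_de``: at least ``fc_threshold``-fold change at any day and
    adjusted p below ``p_threshold``. ``is_de_progressive``: additionally
    at least ``fc_threshold``-fold change between the early and late
    day (defaults: first and second-to-last non-baseline day).
    """
    if not fold_changes.index.equals(adj_pvalues.index):
        raise DesignError("fold-change and p-value tables index different genes")
    log_thr = np.log2(fc_threshold)
    max_abs = fold_changes.abs().max(axis=1)
    is_de = (max_abs >= log_thr) & (adj_pvalues < p_threshold)
    days = list(fold_changes.columns)
    if early_day is None:
        early_day = days[0]
    if late_day is None:
        late_day = days[-2] if len(days) >= 2 else days[-1]
    prog = (fold_changes[late_day] - fold_changes[early_day]).abs() >= log_thr
    return pd.DataFrame({
        "max_abs_log2fc": max_abs,
        "adj_pvalue": adj_pvalues,
        "is_de": is_de,
        "is_de_progressive": is_de & prog,
    })


def typical_expression_range(a_mean_de: pd.Series | np.ndarray,
                             percentiles: tuple[float, float] | None = None,
                             ) -> tuple[float, float]:
    """Expression window spanned by the differentially expressed genes.

    Defaults to the min-max of their A_mean; with ``percentiles=(lo, hi)``
    uses linearly interpolated percentiles instead.
    """
    a = np.asarray(a_mean_de, dtype=float)
    if a.size == 0:
        raise DomainError(
            "empty DE set: pass an explicit (low, high) expression window"
        )
    if percentiles is None:
        return float(a.min()), float(a.max())
    lo, hi = np.percentile(a, percentiles)
    return float(lo), float(hi)


def screen_stable_genes(
    values: pd.DataFrame,
    design: pd.DataFrame,
    window: tuple[float, float],
    change_threshold: float = 0.20,
    cv_threshold: float = 0.01,
    baseline_day=None,
) -> pd.DataFrame:
    """Apply the three-predicate stability screen.

    Keeps genes whose linear-scale relative change versus baseline stays
    below ``change_threshold`` at every day, whose A_mean lies inside
    ``window`` (inclusive), and whose CV_A (sd/mean of the per-array
    values, n-1 denominator, on the stored scale) is below
    ``cv_threshold``. Rows are sorted by ascending CV_A.
    """
    low, high = window
    if not low <= high:
        raise DomainError("window must satisfy low <= high")
    if change_threshold <= 0 or cv_threshold <= 0:
        raise DomainError("thresholds must be positive")
    fc = compute_fold_changes(values, design, baseline_day)
    max_rel_change = (2.0 ** fc - 1.0).abs().max(axis=1)
    a_mean = values.mean(axis=1)
    cv_a = values.std(axis=1, ddof=1) / a_mean
    keep = (
        (max_rel_change < change_threshold)
        & (a_mean >= low) & (a_mean <= high)
        & (cv_a < cv_threshold)
    )
    out = pd.DataFrame({
        "max_rel_change": max_rel_change,
        "a_mean": a_mean,
        "cv_a": cv_a,
    })[keep]
    return out.sort_values("cv_a", kind="mergesort")


class StableGeneScreen(BaseEstimator, TransformerMixin):
    """Scikit-learn style screen for stable reference-gene candidates.

    Parameters
    ----------
    fc_threshold : float, default 2.0
        Linear fold-change threshold of the DE call.
    p_threshold : float, default 0.0005
        Adjusted p-value threshold of the DE call.
    change_threshold : float, default 0.20
        Maximal linear-scale relative change (20%) a candidate may show.
    cv_threshold : float, default 0.01
        Maximal CV_A a candidate may show.
    window : (float, float) or None
        Explicit A_mean window; ``None`` derives it from the DE genes.
    window_percentiles : (float, float) or None
        Percentile bounds for the auto window (``None`` = min-max).
    baseline_day : label or None
        Baseline; ``None`` takes the first day seen in ``y``.

    ``fit(X, y)`` expects ``X`` of shape (n_arrays, n_genes) — a DataFrame
    keeps gene names — and ``y`` the per-array day labels. ``transform``
    selects the candidate columns.

    Attributes
    ----------
    log2_fold_changes_ : DataFrame, genes x non-baseline days.
    pvalues_, adj_pvalues_ : Series per gene.
    de_table_ : DataFrame with is_de / is_de_progressive flags.
    window_ : the (low, high) A_mean window used.
    stable_table_ : screened candidates sorted by CV_A.
    support_ : boolean mask over input genes.
    """

    def __init__(self, fc_threshold=2.0, p_threshold=0.0005,
                 change_threshold=0.20, cv_threshold=0.01,
                 window=None, window_percentiles=None, baseline_day=None,
                 pvalues=None):
        self.fc_threshold = fc_threshold
        self.p_threshold = p_threshold
        self.change_threshold = change_threshold
        self.cv_threshold = cv_threshold
        self.window = window
        self.window_percentiles = window_percentiles
        self.baseline_day = baseline_day
        self.pvalues = pvalues  # optional externally computed p-values

    def _as_values(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        genes = [f"g{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X.T, index=genes,
                            columns=[f"a{i}" for i in range(X.shape[0])])

    def fit(self, X, y):
        values = self._as_values(X)
        y = np.asarray(y)
        if len(y) != values.shape[1]:
            raise DesignError("y must give one day label per array")
        design = pd.DataFrame({"sample": values.columns, "day": y})
        design["replicate"] = design.groupby("day").cumcount() + 1

        self.genes_ = values.index.to_numpy()
        self.log2_fold_changes_ = compute_fold_changes(values, design,
                                                       self.baseline_day)
        if self.pvalues is not None:
            pv = pd.Series(np.asarray(self.pvalues, float), index=values.index)
        else:
            pv = anova_pvalues(values, design)
        self.pvalues_ = pv
        self.adj_pvalues_ = adjust_pvalues(pv)
        self.de_table_ = select_de_genes(
            self.log2_fold_changes_, self.adj_pvalues_,
            self.fc_threshold, self.p_threshold,
        )
        self.a_mean_ = values.mean(axis=1)
        if self.window is not None:
            self.window_ = (float(self.window[0]), float(self.window[1]))
        else:
            de_a = self.a_mean_[self.de_table_["is_de"]]
            self.window_ = typical_expression_range(de_a, self.window_percentiles)
        self.stable_table_ = screen_stable_genes(
            values, design, self.window_,
            self.change_threshold, self.cv_threshold, self.baseline_day,
        )
        self.support_ = values.index.isin(self.stable_table_.index)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]
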