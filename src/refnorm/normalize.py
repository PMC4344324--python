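"""Reference-gene normalization and CV-reduction evaluation.

Targets measured across a (day x biological replicate) grid are divided
by a per-sample normalization factor NF — the geometric mean of the
chosen reference genes' levels in that sample. Variation across the
replicates of each day is summarized by the coefficient of variation
(sample s.d. with the n-1 denominator over the arithmetic mean), and the
benefit of a reference combination is the percent reduction

    CV_reduce = 100 * (CV_raw - CV_norm) / CV_raw

which can be negative when normalization worsens the spread. Time-course
profiles are reported as fold changes relative to the baseline day,
either per replicate or on replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DesignError, DomainError

__all__ = [
    "geometric_mean_nf",
    "normalize_series",
    "scale_to_day0",
    "cv",
    "cv_reduction",
    "build_report",
    "NormalizationReport",
    "ReferenceNormalizer",
]


def geometric_mean_nf(ref_values: pd.DataFrame, subset=None) -> pd.Series:
    """Per-sample normalization factor: geometric mean of reference levels.

    ``ref_values`` is genes x samples; ``subset`` selects the reference
    genes (default: all rows). Values must be strictly positive.
    """
    sub = ref_values if subset is None else ref_values.loc[list(subset)]
    if sub.shape[0] == 0:
        raise DomainError("reference subset is empty")
    bad = np.argwhere(sub.to_numpy() <= 0)
    if bad.size:
        g, s = bad[0]
        raise DomainError(
            f"non-positive reference value for gene {sub.index[g]!r} "
            f"in sample {sub.columns[s]!r}"
        )
    return pd.Series(gmean(sub.to_numpy(), axis=0), index=sub.columns, name="NF")


def normalize_series(raw: pd.Series, nf: pd.Series) -> pd.Series:
    """Divide a target's per-sample values by the normalization factor."""
    missing = set(raw.index) - set(nf.index)
    if missing:
        raise DesignError(f"no NF for samples: {sorted(missing)[:5]}")
    return raw / nf.reindex(raw.index)


def cv(values) -> float:
    """Coefficient of variation: sample s.d. (n-1) over arithmetic mean."""
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise DomainError("CV needs at least 2 replicate values")
    mean = a.mean()
    if mean == 0:
        raise DomainError("CV undefined: replicate mean is zero")
    return float(a.std(ddof=1) / mean)


def cv_reduction(cv_raw: float, cv_norm: float) -> float:
    """Percent CV reduction, 100*(CV_raw - CV_norm)/CV_raw (may be < 0)."""
    if cv_raw <= 0:
        raise DomainError("CV reduction undefined for cv_raw <= 0")
    return 100.0 * (cv_raw - cv_norm) / cv_raw


def _series_grid(series: pd.DataFrame) -> pd.DataFrame:
    for col in ("day", "replicate", "value"):
        if col not in series.columns:
            raise DesignError(f"series table lacks a '{col}' column")
    if series.duplicated(["day", "replicate"]).any():
        raise DesignError("duplicate (day, replicate) measurements")
    return series


def scale_to_day0(series: pd.DataFrame, mode: str = "per_replicate",
                  baseline_day=None) -> pd.DataFrame:
    """Express a time course as fold change relative to the baseline day.

    ``mode='per_replicate'`` divides each replicate's trajectory by its
    own baseline value; ``mode='mean'`` divides day means by the baseline
    mean (one profile). Baseline defaults to the first day in the table.
    """
    series = _series_grid(series)
    days = list(dict.fromkeys(series["day"]))
    if baseline_day is None:
        baseline_day = days[0]
    base = series[series["day"] == baseline_day]
    if base.empty:
        raise DesignError(f"baseline day {baseline_day!r} absent")
    if mode == "per_replicate":
        base_by_rep = base.set_index("replicate")["value"]
        if (base_by_rep == 0).any():
            raise DomainError("zero baseline value")
        out = series.copy()
        out["fold"] = out["value"] / out["replicate"].map(base_by_rep).to_numpy()
        return out[["day", "replicate", "fold"]]
    if mode == "mean":
        base_mean = base["value"].mean()
        if base_mean == 0:
            raise DomainError("zero baseline mean")
        day_means = series.groupby("day", sort=False)["value"].mean()
        return pd.DataFrame({"day": day_means.index,
                             "fold": (day_means / base_mean).to_numpy()})
    raise DomainError("mode must be 'per_replicate' or 'mean'")


@dataclass
class NormalizationReport:
    """CV table and baseline-scaled profiles for a set of targets.

    Attributes
    ----------
    cv_table : DataFrame
        One row per (target, day, combo): ``cv_raw``, ``cv_norm``,
        ``cv_reduce_pct``.
    profiles : DataFrame
        Long format, per (target, day, replicate): baseline-scaled
        ``raw_fold`` and ``norm_fold`` (normalized with the full
        reference set).
    references : tuple of gene names used for the profile normalization.
    """

    cv_table: pd.DataFrame
    profiles: pd.DataFrame
    references: tuple


def _combo_label(combo) -> str:
    return "+".join(combo)


def build_report(
    measurements: pd.DataFrame,
    targets,
    references,
    combos,
    scale_mode: str = "per_replicate",
    baseline_day=None,
) -> NormalizationReport:
    """Evaluate reference combinations on measured time courses.

    Parameters
    ----------
    measurements : DataFrame
        Tidy table with columns ``gene``, ``day``, ``replicate``,
        ``value`` covering every target and reference on a complete
        day x replicate grid.
    targets, references : iterables of gene names.
    combos : iterable of reference subsets (tuples of gene names).
    scale_mode : 'per_replicate' or 'mean' for the profile scaling.
    """
    for col in ("gene", "day", "replicate", "value"):
        if col not in measurements.columns:
            raise DesignError(f"measurement table lacks a '{col}' column")
    combos = [tuple(c) for c in combos]
    known = set(measurements["gene"])
    for combo in combos:
        unknown = set(combo) - known
        if unknown:
            raise DesignError(f"combo {combo} references unknown genes {unknown}")
    wide = measurements.pivot_table(index="gene",
                                    columns=["day", "replicate"],
                                    values="value")
    if wide.isna().any().any():
        raise DesignError("incomplete day x replicate grid")
    days = list(dict.fromkeys(measurements["day"]))

    nf_by_combo = {c: geometric_mean_nf(wide, c) for c in combos}
    nf_full = geometric_mean_nf(wide, tuple(references))

    cv_rows = []
    prof_rows = []
    for target in targets:
        raw = wide.loc[target]
        norm_full = normalize_series(raw, nf_full)
        for day in days:
            cv_raw = cv(raw[day])
            for combo in combos:
                normed = normalize_series(raw, nf_by_combo[combo])
                cv_norm = cv(normed[day])
                cv_rows.append({
                    "target": target, "day": day,
                    "combo": _combo_label(combo),
                    "cv_raw": cv_raw, "cv_norm": cv_norm,
                    "cv_reduce_pct": cv_reduction(cv_raw, cv_norm),
                })
        raw_series = raw.rename("value").reset_index()
        norm_series = norm_full.rename("value").reset_index()
        raw_prof = scale_to_day0(raw_series, scale_mode, baseline_day)
        norm_prof = scale_to_day0(norm_series, scale_mode, baseline_day)
        keys = [c for c in ("day", "replicate") if c in raw_prof.columns]
        merged = raw_prof.merge(norm_prof, on=keys, suffixes=("_raw", "_norm"))
        merged.insert(0, "target", target)
        prof_rows.append(merged.rename(columns={"fold_raw": "raw_fold",
                                                "fold_norm": "norm_fold"}))

    return NormalizationReport(
        cv_table=pd.DataFrame(cv_rows),
        profiles=pd.concat(prof_rows, ignore_index=True),
        references=tuple(references),
    )


class ReferenceNormalizer(BaseEstimator, TransformerMixin):
    """Divide every gene by the geometric mean of reference genes.

    ``fit(X)`` expects ``X`` of shape (n_samples, n_genes); a DataFrame
    keeps gene names, otherwise ``reference_genes`` are column indices.
    ``transform`` computes, per row (sample), the geometric mean of the
    reference columns and divides the whole row by it, yielding
    dimensionless relative levels.
    """

    def __init__(self, reference_genes=()):
        self.reference_genes = reference_genes

    def fit(self, X, y=None):
        refs = list(self.reference_genes)
        if not refs:
            raise DomainError("reference_genes must be non-empty")
        if isinstance(X, pd.DataFrame):
            unknown = set(refs) - set(X.columns)
            if unknown:
                raise DesignError(f"unknown reference genes: {sorted(unknown)}")
            self.reference_indices_ = [X.columns.get_loc(g) for g in refs]
        else:
            self.reference_indices_ = [int(g) for g in refs]
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        ref = arr[:, self.reference_indices_]
        if (ref <= 0).any():
            raise DomainError("non-positive reference value")
        nf = gmean(ref, axis=1)
        out = arr / nf[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out
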