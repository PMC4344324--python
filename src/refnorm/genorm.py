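"""Gene-expression stability statistics in the geNorm tradition.

For a matrix of strictly positive relative quantities q (genes x samples):

* pairwise variation ``V_jk`` — the sample standard deviation (n-1
  denominator) over samples of ``log2(q_j / q_k)``;
* the stability measure ``M_j`` — the mean of ``V_jk`` over all other
  genes; lower M means more stable expression (the customary suitability
  guideline is M below 1.5);
* a stepwise ranking that repeatedly drops the least stable gene and
  recomputes M, leaving an inseparable most-stable pair;
* normalization factors ``NF_n`` (geometric mean of the n top-ranked
  genes per sample) and the pairwise variation series ``V_{n/n+1}``
  used to choose how many reference genes are worth including (values
  below 0.15 indicate that adding a gene changes little).

Because every statistic is built from log ratios, M and V are invariant
under per-sample and per-gene rescaling of the quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DesignError, DomainError

__all__ = [
    "relative_quantity_from_cq",
    "stability_measure",
    "rank_by_stepwise_exclusion",
    "pairwise_v_series",
    "GeNormSelector",
]


def relative_quantity_from_cq(cq: pd.DataFrame,
                              efficiency: float | dict = 2.0) -> pd.DataFrame:
    """Transform a Cq table into relative quantities.

    Technical replicates are first averaged on the Cq scale; then
    ``q(g, s) = E_g ** (min_s Cq(g, .) - Cq(g, s))`` so the best-expressed
    sample of every gene gets q = 1. ``efficiency`` may be a single value
    or a per-gene mapping; values must lie in (1, 2].

    Parameters
    ----------
    cq : DataFrame with columns ``gene``, ``sample``, ``tech_rep``, ``cq``.

    Returns
    -------
    DataFrame of quantities, genes x samples.
    """
    for col in ("gene", "sample", "cq"):
        if col not in cq.columns:
            raise DesignError(f"Cq table lacks a '{col}' column")
    mean_cq = cq.pivot_table(index="gene", columns="sample", values="cq",
                             aggfunc="mean")
    if mean_cq.isna().any().any():
        missing = [(g, s) for (g, s) in zip(*np.where(mean_cq.isna()))]
        raise DesignError(
            f"missing Cq for {len(missing)} (gene, sample) pairs; no imputation"
        )

    def _eff(gene: str) -> float:
        e = efficiency.get(gene, 2.0) if isinstance(efficiency, dict) else efficiency
        if not 1 < e <= 2:
            raise DomainError(f"efficiency for {gene} must be in (1, 2]")
        return float(e)

    effs = np.array([_eff(g) for g in mean_cq.index])
    delta = mean_cq.min(axis=1).to_numpy()[:, None] - mean_cq.to_numpy()
    q = effs[:, None] ** delta
    return pd.DataFrame(q, index=mean_cq.index, columns=mean_cq.columns)


def _validate_quantities(q: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if not isinstance(q, pd.DataFrame):
        q = pd.DataFrame(np.asarray(q, dtype=float))
    if (q.to_numpy() <= 0).any() or not np.isfinite(q.to_numpy()).all():
        raise DomainError("quantities must be strictly positive and finite")
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise DomainError("need at least 2 genes and 2 samples")
    return q


def stability_measure(q: pd.DataFrame | np.ndarray
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene M values and the pairwise-variation matrix V.

    Returns ``(M, V)`` where ``V.loc[j, k]`` is the standard deviation of
    ``log2(q_j/q_k)`` across samples and ``M_j`` its mean over ``k != j``.
    """
    q = _validate_quantities(q)
    logq = np.log2(q.to_numpy())
    genes = q.index
    # (G, G, S) log-ratio tensor is fine for panel-sized G
    diffs = logq[:, None, :] - logq[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    m = v.sum(axis=1) / (len(genes) - 1)
    return (pd.Series(m, index=genes, name="M"),
            pd.DataFrame(v, index=genes, columns=genes))


def rank_by_stepwise_exclusion(q: pd.DataFrame | np.ndarray
                               ) -> tuple[list, pd.Series]:
    """Stability ranking by iterated worst-gene exclusion.

    Repeatedly recomputes M on the remaining genes and removes the one
    with the largest M (exact ties: the gene later in input order goes).
    The final two genes cannot be separated and share rank 1; the gene
    removed at step r (counting from the end) gets rank r + 1.

    Returns
    -------
    ranking : list of gene names, most to least stable (the tied pair
        first, in input order).
    ranks : Series of integer ranks per gene (two genes hold rank 1).
    """
    q = _validate_quantities(q)
    genes = list(q.index)
    if len(genes) == 2:
        return genes, pd.Series([1, 1], index=genes, name="rank")
    remaining = list(genes)
    removed: list = []
    while len(remaining) > 2:
        m, _ = stability_measure(q.loc[remaining])
        worst_m = m.max()
        # exact-tie rule: later input position loses
        worst = [g for g in remaining if m[g] == worst_m][-1]
        remaining.remove(worst)
        removed.append(worst)
    ranking = remaining + removed[::-1]
    ranks = pd.Series(0, index=pd.Index(genes), name="rank")
    ranks[remaining] = 1
    for i, g in enumerate(removed[::-1]):
        ranks[g] = i + 2
    return ranking, ranks[genes]


def pairwise_v_series(q: pd.DataFrame | np.ndarray,
                      ranking: list | None = None) -> pd.Series:
    """Pairwise variation V_{n/n+1} between successive normalization factors.

    ``NF_n(s)`` is the geometric mean over the n top-ranked genes of
    ``q(., s)``; ``V_{n/n+1}`` is the standard deviation over samples of
    ``log2(NF_n / NF_{n+1})``, for n = 2 .. G-1.
    """
    q = _validate_quantities(q)
    if ranking is None:
        ranking, _ = rank_by_stepwise_exclusion(q)
    if len(ranking) < 3:
        raise DomainError("V series needs at least 3 genes")
    logq = np.log2(q.loc[list(ranking)].to_numpy())
    out = {}
    for n in range(2, len(ranking)):
        log_nf_n = logq[:n].mean(axis=0)
        log_nf_n1 = logq[: n + 1].mean(axis=0)
        out[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return pd.Series(out, name="V").rename_axis("n")


def normalization_factor(q: pd.DataFrame, genes: list) -> pd.Series:
    """Per-sample geometric mean of the given genes' quantities."""
    q = _validate_quantities(q)
    sub = np.log2(q.loc[list(genes)].to_numpy())
    return pd.Series(2.0 ** sub.mean(axis=0), index=q.columns, name="NF")


class GeNormSelector(BaseEstimator, TransformerMixin):
    """Select the most stably expressed genes, scikit-learn style.

    ``fit(X)`` expects ``X`` of shape (n_samples, n_genes) with strictly
    positive relative quantities (a DataFrame keeps gene names).
    ``transform`` keeps the ``n_select`` top-ranked columns.

    Parameters
    ----------
    n_select : int, default 2
        Number of reference genes to retain.

    Attributes
    ----------
    m_values_ : Series of per-gene M.
    pairwise_variation_ : DataFrame V (genes x genes).
    ranking_ : gene names, most to least stable.
    ranks_ : integer ranks (final pair tied at 1).
    v_series_ : Series V_{n/n+1} indexed by n (when >= 3 genes).
    """

    def __init__(self, n_select: int = 2):
        self.n_select = n_select

    def _as_q(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X.T, index=[f"g{j}" for j in range(X.shape[1])])

    def fit(self, X, y=None):
        q = self._as_q(X)
        self.genes_ = q.index.to_numpy()
        self.m_values_, self.pairwise_variation_ = stability_measure(q)
        self.ranking_, self.ranks_ = rank_by_stepwise_exclusion(q)
        if q.shape[0] >= 3:
            self.v_series_ = pairwise_v_series(q, self.ranking_)
        else:
            self.v_series_ = pd.Series(dtype=float, name="V")
        if not 1 <= self.n_select <= len(self.ranking_):
            raise DomainError("n_select out of range")
        self.selected_genes_ = list(self.ranking_[: self.n_select])
        self.support_ = q.index.isin(self.selected_genes_)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]
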