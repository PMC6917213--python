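"""Count normalization, differential expression and PCA summaries.

The DE engine is a transparent negative-binomial Wald test: counts are
normalized with median-of-ratios size factors, per-gene dispersion is
estimated by method of moments from the pooled within-group variance, the
effect is the log2 ratio of group means with a pseudo-count of 0.5, and
the Wald statistic uses a delta-method variance.  Selection applies the
study thresholds: |log2 fold change| ≥ 2 in at least one contrast, raw
p < 0.05 and Benjamini–Hochberg q < 0.05.  Genes failing the activity
filter (≥ 10 reads in ≥ 2 samples) are reported with NaN p/q and are
excluded from the BH family.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import InputError, NormalizationError

__all__ = [
    "size_factors",
    "active_genes",
    "de_test",
    "bh_adjust",
    "select_de",
    "top_variance_pca",
    "annotated_fraction",
]

PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    Ratios are taken against the per-gene geometric mean over genes
    expressed in every sample.  Raises :class:`NormalizationError` when no
    such gene exists.
    """
    arr = counts.to_numpy(float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError("no gene expressed in all samples")
    logs = np.log(arr[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def active_genes(counts: pd.DataFrame, min_reads: int = 10, min_samples: int = 2) -> List[str]:
    """Genes with at least ``min_reads`` reads in at least ``min_samples`` samples."""
    mask = (counts >= min_reads).sum(axis=1) >= min_samples
    return list(counts.index[mask])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    baseline: str,
    contrast: str,
    min_reads: int = 10,
    min_samples: int = 2,
) -> pd.DataFrame:
    """NB Wald test of ``contrast`` vs ``baseline`` condition groups.

    ``meta`` must carry a ``condition`` column indexed by sample.  Returns
    a DETable with one row per gene: ``baseMean`` (mean normalized count),
    ``log2fc`` (contrast vs baseline, pseudo-count 0.5), ``p`` and BH ``q``
    (NaN for genes failing the activity filter).
    """
    for label in (baseline, contrast):
        if label not in set(meta["condition"]):
            raise InputError(f"unknown condition label: {label!r}")
    base_samples = meta.index[meta["condition"] == baseline]
    con_samples = meta.index[meta["condition"] == contrast]
    if len(base_samples) < 2 or len(con_samples) < 2:
        raise InputError("both condition groups need at least two samples")
    sub = counts[[*base_samples, *con_samples]]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)

    yb = norm[base_samples].to_numpy(float)
    yc = norm[con_samples].to_numpy(float)
    n1, n2 = yb.shape[1], yc.shape[1]
    m1 = yb.mean(axis=1)
    m2 = yc.mean(axis=1)
    s2 = ((n1 - 1) * yb.var(axis=1, ddof=1) + (n2 - 1) * yc.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    mu = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum((s2 - mu) / np.square(mu), 0.0)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)

    log2fc = np.log2(m2 + PSEUDOCOUNT) - np.log2(m1 + PSEUDOCOUNT)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        (m1 + alpha * m1**2) / (n1 * np.square(m1 + PSEUDOCOUNT))
        + (m2 + alpha * m2**2) / (n2 * np.square(m2 + PSEUDOCOUNT))
    ) / ln2sq
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    # t reference with the pooled-variance df: the moment dispersion
    # estimate is noisy at small n and a normal reference would be
    # anti-conservative
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)

    active = set(active_genes(sub, min_reads=min_reads, min_samples=min_samples))
    is_active = counts.index.isin(active)
    p = np.where(is_active, p, np.nan)
    q = np.full_like(p, np.nan)
    if is_active.any():
        q[is_active] = bh_adjust(p[is_active])

    return pd.DataFrame(
        {
            "baseMean": (n1 * m1 + n2 * m2) / (n1 + n2),
            "log2fc": log2fc,
            "p": p,
            "q": q,
        },
        index=counts.index,
    )


def select_de(
    tables: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    lfc_thresh: float = 2.0,
    q_thresh: float = 0.05,
    p_thresh: float = 0.05,
) -> List[str]:
    """Genes passing |log2fc| ≥ ``lfc_thresh`` with p and q below threshold
    in at least one contrast.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise InputError("no DE tables supplied")
    selected: set = set()
    for tab in tables:
        ok = (
            (tab["log2fc"].abs() >= lfc_thresh)
            & (tab["p"] < p_thresh)
            & (tab["q"] < q_thresh)
        )
        selected.update(tab.index[ok.fillna(False)])
    return [g for g in tables[0].index if g in selected] + sorted(
        selected.difference(tables[0].index)
    )


def top_variance_pca(
    expr: pd.DataFrame,
    n_top: int = 500,
    min_reads_all: Optional[float] = 500,
):
    """First two principal components over the highest-variance genes.

    Genes are filtered to those with values strictly above
    ``min_reads_all`` in every sample (pass ``None`` to skip), ranked by
    variance, and the top ``n_top`` are centered per gene before the SVD.
    Returns ``(coords, explained)``: a samples × 2 DataFrame and the
    explained-variance fractions of PC1 and PC2.
    """
    if expr.shape[1] < 2:
        raise InputError("PCA needs at least two samples")
    sub = expr
    if min_reads_all is not None:
        sub = expr[(expr > min_reads_all).all(axis=1)]
    if n_top > sub.shape[0]:
        raise InputError(
            f"n_top={n_top} exceeds the {sub.shape[0]} genes passing the read filter"
        )
    var = sub.var(axis=1, ddof=1)
    top = sub.loc[var.sort_values(ascending=False).index[:n_top]]
    centered = top.sub(top.mean(axis=1), axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(centered.to_numpy(float).T)
    coords_df = pd.DataFrame(coords, index=expr.columns, columns=["PC1", "PC2"])
    return coords_df, pca.explained_variance_ratio_.copy()


def annotated_fraction(n_detected: int, n_total: int) -> int:
    """Percent of the annotated universe detected, to the nearest integer."""
    if n_total <= 0 or n_detected < 0 or n_detected > n_total:
        raise InputError("need 0 <= n_detected <= n_total with n_total > 0")
    return int(round(100.0 * n_detected / n_total))
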