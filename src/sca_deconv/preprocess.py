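"""Filtering, normalization, signature construction and feature selection.

The pipeline mirrors the standard single-cell workflow: drop low-quality
cells and near-silent genes, log-normalize with a fixed size factor,
average normalized profiles per cell type into a pseudo-bulk signature,
and restrict the signature to the most variable genes of the reference.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, NormalizedMatrix, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_cells_genes",
    "lognormalize",
    "build_pseudobulk",
    "select_hvgs",
    "wilcoxon_markers",
    "downsample_features",
]


def filter_cells_genes(
    m: CountMatrix, min_genes_per_cell: int = 200, min_cells_per_gene: int = 3
) -> CountMatrix:
    """Drop cells detecting few genes, then genes expressed in few cells."""
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValueError("cannot filter an empty count matrix")
    detected = (m.values > 0).sum(axis=0)
    cell_keep = detected >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError(
            f"no cell detects >= {min_genes_per_cell} genes; all cells removed"
        )
    out = m.subset_cells(np.flatnonzero(cell_keep))
    expressed_in = (out.values > 0).sum(axis=1)
    gene_keep = expressed_in >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"no gene is expressed in >= {min_cells_per_gene} cells; all genes removed"
        )
    return out.subset_genes(np.flatnonzero(gene_keep))


def lognormalize(m: CountMatrix, size_factor: float = 1e4) -> NormalizedMatrix:
    """Per-cell total-count scaling to ``size_factor`` followed by log1p.

    Entry (g, j) becomes ln(1 + size_factor * x_gj / colsum_j); all-zero
    cells map to all-zero columns.
    """
    if size_factor < 0:
        raise ValueError("size_factor must be nonnegative")
    totals = m.values.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(size_factor * m.values / safe[None, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        labels=None if m.labels is None else m.labels.copy(),
        size_factor=float(size_factor),
    )


def build_pseudobulk(
    nm: NormalizedMatrix, labels: Sequence[str] | None = None
) -> SignatureMatrix:
    """Average normalized profiles per cell type (columns in sorted label order)."""
    if labels is None:
        labels = nm.labels
    if labels is None:
        raise ValueError("per-cell labels are required to build a pseudo-bulk")
    labels = np.asarray(labels, dtype=object)
    if labels.size != nm.n_cells:
        raise ValueError("one label per cell required")
    types = sorted(set(labels))
    cols = np.empty((nm.n_genes, len(types)))
    for c, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        cols[:, c] = nm.values[:, mask].mean(axis=1)
    return SignatureMatrix(
        values=cols, gene_ids=nm.gene_ids.copy(), type_names=np.array(types, dtype=object)
    )


def select_hvgs(nm_ref: NormalizedMatrix | SignatureMatrix, n: int = 2000) -> np.ndarray:
    """Rank genes by trend-standardized dispersion; return the top ``n`` indices.

    A lowess trend of log variance against log mean absorbs the
    mean-variance relationship; genes are scored by their residual above
    the trend so the ranking reflects variation across columns beyond
    what expression level alone predicts. Applied to a log-normalized
    single-cell matrix this is the usual highly-variable-gene criterion;
    applied to a pseudo-bulk signature (columns = cell type profiles) it
    ranks genes by their variation across the C cell types, which is how
    the annotation pipeline restricts the signature to its 2000 most
    informative rows. Deterministic; ties break on gene identifier.
    """
    if n <= 0:
        raise ValueError("number of HVGs must be positive")
    if nm_ref.values.shape[1] < 2:
        raise ValueError("need at least two columns to rank variable genes")
    x = nm_ref.values
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)

    score = np.full(x.shape[0], -np.inf)
    informative = (var > 0) & (mean > 0)
    if informative.sum() > 10:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        lm = np.log10(mean[informative] + 1e-12)
        lv = np.log10(var[informative])
        trend = lowess(lv, lm, frac=0.3, it=2, xvals=lm)
        score[informative] = lv - trend
    elif informative.any():
        score[informative] = var[informative]

    order = np.lexsort((nm_ref.gene_ids.astype(str), -score))
    return np.sort(order[: min(n, x.shape[0])])


def wilcoxon_markers(
    nm: NormalizedMatrix,
    labels: Sequence[str] | None = None,
    top_k: int = 10,
    only_pos: bool = True,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker detection.

    For each type, genes expressed in at least ``min_pct`` of cells of
    either group and with natural-log fold change of back-transformed
    group means above ``logfc_threshold`` are tested with a two-sided
    Wilcoxon rank-sum test; the ``top_k`` genes per type are returned
    ranked by p-value, then |logFC|, then gene id.
    """
    if labels is None:
        labels = nm.labels
    if labels is None:
        raise ValueError("labels required for marker selection")
    labels = np.asarray(labels, dtype=object)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("marker selection needs at least two cell types")

    rows = []
    expm1 = np.expm1(nm.values)
    for t in types:
        in_mask = labels == t
        n_in = int(in_mask.sum())
        if n_in < 3:
            warnings.warn(f"cell type {t!r} has fewer than 3 cells; skipped")
            continue
        x_in = nm.values[:, in_mask]
        x_out = nm.values[:, ~in_mask]
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        mean_in = expm1[:, in_mask].mean(axis=1)
        mean_out = expm1[:, ~in_mask].mean(axis=1)
        logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)

        passes = np.maximum(pct_in, pct_out) >= min_pct
        passes &= (logfc > logfc_threshold) if only_pos else (np.abs(logfc) > logfc_threshold)
        idx = np.flatnonzero(passes)
        if idx.size == 0:
            continue
        # exact null distribution when both groups are small and tie-free,
        # normal approximation with tie correction otherwise
        n_out = x_out.shape[1]

        def _pvalue(a: np.ndarray, b: np.ndarray) -> float:
            exact = (
                a.size <= 10
                and b.size <= 10
                and np.unique(np.concatenate([a, b])).size == a.size + b.size
            )
            return float(
                stats.mannwhitneyu(
                    a, b, alternative="two-sided",
                    method="exact" if exact else "asymptotic",
                ).pvalue
            )

        pvals = np.array([_pvalue(x_in[g], x_out[g]) for g in idx])
        sub = pd.DataFrame(
            {
                "cell_type": t,
                "gene": nm.gene_ids[idx],
                "p_value": pvals,
                "log_fc": logfc[idx],
                "pct_in": pct_in[idx],
                "pct_out": pct_out[idx],
            }
        )
        sub = (
            sub.assign(_abs_fc=sub["log_fc"].abs())
            .sort_values(["p_value", "_abs_fc", "gene"], ascending=[True, False, True])
            .drop(columns="_abs_fc")
            .head(top_k)
        )
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["cell_type", "gene", "p_value", "log_fc", "pct_in", "pct_out"]
        )
    return pd.concat(rows, ignore_index=True)


def downsample_features(m: CountMatrix, n_keep: int, seed: int = 0) -> CountMatrix:
    """Stratified random gene downsampling preserving the log-count profile.

    Genes are binned into 20 equal-width bins of ln(1 + total count); the
    kept set is allocated to bins proportionally (largest remainder) and
    sampled uniformly without replacement within each bin.
    """
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > m.n_genes:
        raise ValueError(f"cannot keep {n_keep} of {m.n_genes} genes")
    if n_keep == m.n_genes:
        return m

    log_totals = np.log1p(m.values.sum(axis=1).astype(float))
    n_bins = 20
    edges = np.linspace(log_totals.min(), log_totals.max(), n_bins + 1)
    bins = np.clip(np.digitize(log_totals, edges[1:-1]), 0, n_bins - 1)

    occupied = np.unique(bins)
    counts = np.array([(bins == b).sum() for b in occupied])
    exact = n_keep * counts / counts.sum()
    alloc = np.floor(exact).astype(int)
    remainder = n_keep - alloc.sum()
    order = np.argsort(-(exact - alloc), kind="stable")
    alloc[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for b, k in zip(occupied, alloc):
        members = np.flatnonzero(bins == b)
        k = min(k, members.size)
        keep.append(rng.choice(members, size=k, replace=False))
    idx = np.sort(np.concatenate(keep))
    return m.subset_genes(idx)
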