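"""Deconvolution-style reference annotation of single cells.

Two estimators map a query cell's normalized profile y onto the columns
b_c of a pseudo-bulk signature matrix H under the mixture model
y = sum_c w_c b_c + eps, and assign the type with the largest weight:

* CP (constrained projection) minimizes ||y - H w||^2 over the
  probability simplex (w >= 0, sum w = 1), a quadratic program.
* RPC (robust partial correlations) fits a Huber-loss robust linear
  regression of y on H (with intercept) by iteratively reweighted least
  squares; the unconstrained slope coefficients are the weights.

Because each query cell is one cell type rather than a mixture, the
largest weight is read as the cell's identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import CountMatrix, NormalizedMatrix, SignatureMatrix
from . import preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "WeightEstimate",
    "AnnotationResult",
    "align_genes",
    "fit_cp",
    "fit_rpc",
    "assign_labels",
    "annotate",
]

#: 95%-efficiency Huber tuning constant (residuals scaled by MAD)
HUBER_C = 1.345

#: fewest shared genes for which a projection is considered informative
MIN_SHARED_GENES = 50


@dataclass
class WeightEstimate:
    """Per-cell weight vector, assigned label and fit residual."""

    weights: np.ndarray
    label: str
    residual_norm: float


@dataclass
class AnnotationResult:
    """Annotation of a query: one WeightEstimate row per cell."""

    cell_ids: np.ndarray
    type_names: np.ndarray
    weights: np.ndarray  # cells x C
    labels: np.ndarray
    residual_norms: np.ndarray
    method: str
    genes_used: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, columns=list(self.type_names))
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "predicted_label", self.labels)
        df["residual_norm"] = self.residual_norms
        return df


def align_genes(
    H: SignatureMatrix, query: NormalizedMatrix
) -> tuple[SignatureMatrix, NormalizedMatrix]:
    """Restrict signature and query to their shared genes, same order."""
    sig_pos = {g: i for i, g in enumerate(H.gene_ids)}
    shared = [g for g in query.gene_ids if g in sig_pos]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between signature and query "
            f"(need >= {MIN_SHARED_GENES}); the signature is uninformative"
        )
    q_pos = {g: i for i, g in enumerate(query.gene_ids)}
    h_idx = np.array([sig_pos[g] for g in shared])
    q_idx = np.array([q_pos[g] for g in shared])
    logger.info("gene alignment kept %d shared genes", len(shared))
    return H.subset_genes(h_idx), query.subset_genes(q_idx)


def _solve_simplex_qp(Q: np.ndarray, c: np.ndarray) -> np.ndarray:
    """min 0.5 w'Qw - c'w  s.t.  w >= 0, sum w = 1 (SLSQP, tight tolerance)."""
    C = Q.shape[0]
    w0 = np.full(C, 1.0 / C)
    res = optimize.minimize(
        fun=lambda w: 0.5 * w @ Q @ w - c @ w,
        x0=w0,
        jac=lambda w: Q @ w - c,
        method="SLSQP",
        bounds=[(0.0, None)] * C,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(C)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success and res.status != 8:
        raise RuntimeError(
            "constrained projection failed to converge "
            f"({res.message}); signature condition number {np.linalg.cond(Q):.3g}"
        )
    w = np.clip(res.x, 0.0, None)
    return w


def fit_cp(
    y: np.ndarray,
    H: SignatureMatrix,
    sum_constraint: Literal["eq", "le"] = "eq",
) -> WeightEstimate:
    """Constrained projection of one profile onto the signature simplex.

    ``sum_constraint='le'`` relaxes the sum-to-one equality to
    sum w <= 1, the convention of some deconvolution implementations.
    """
    y = np.asarray(y, dtype=float)
    A = H.values
    if A.shape[0] != y.size:
        raise ValueError("profile and signature must be gene-aligned")
    if H.n_types < 2:
        raise ValueError("need at least two cell types to project onto")
    Q = A.T @ A
    c = A.T @ y
    if sum_constraint == "eq":
        w = _solve_simplex_qp(Q, c)
    elif sum_constraint == "le":
        C = Q.shape[0]
        res = optimize.minimize(
            fun=lambda w: 0.5 * w @ Q @ w - c @ w,
            x0=np.full(C, 1.0 / (C + 1)),
            jac=lambda w: Q @ w - c,
            method="SLSQP",
            bounds=[(0.0, None)] * C,
            constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                          "jac": lambda w: -np.ones(C)}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        w = np.clip(res.x, 0.0, None)
    else:
        raise ValueError(f"unknown sum constraint {sum_constraint!r}")
    label = _argmax_label(w, H.type_names)
    resid = float(np.linalg.norm(y - A @ w))
    return WeightEstimate(weights=w, label=label, residual_norm=resid)


def _huber_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = HUBER_C,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Huber M-estimate by IRLS with MAD residual scale."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    exact_floor = 1e-10 * (np.median(np.abs(y)) + 1.0)
    for _ in range(max_iter):
        r = y - X @ beta
        scale = np.median(np.abs(r)) / 0.6745
        if scale <= exact_floor:
            return beta  # (near-)exact fit: Huber coincides with least squares
        u = np.abs(r) / scale
        with np.errstate(divide="ignore"):
            w = np.where(u <= c, 1.0, c / np.maximum(u, np.finfo(float).tiny))
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        delta = np.max(
            np.abs(beta_new - beta) / np.maximum(np.abs(beta), 1e-12)
        )
        beta = beta_new
        if delta < tol:
            return beta
    warnings.warn("Huber IRLS did not converge; returning last iterate")
    return beta


def fit_rpc(y: np.ndarray, H: SignatureMatrix) -> WeightEstimate:
    """Robust (Huber) regression of one profile on the signature columns.

    Coefficients are unconstrained (may be negative); the intercept
    absorbs global shifts between platforms and is excluded from the
    argmax.
    """
    y = np.asarray(y, dtype=float)
    A = H.values
    if A.shape[0] != y.size:
        raise ValueError("profile and signature must be gene-aligned")
    if H.n_types < 2:
        raise ValueError("need at least two cell types to regress on")
    cond = np.linalg.cond(A)
    if cond > 1e10:
        warnings.warn(f"signature columns nearly collinear (condition number {cond:.3g})")
    X = np.column_stack([np.ones(A.shape[0]), A])
    beta = _huber_irls(X, y)
    w = beta[1:]
    label = _argmax_label(w, H.type_names)
    resid = float(np.linalg.norm(y - X @ beta))
    return WeightEstimate(weights=w, label=label, residual_norm=resid)


def _argmax_label(w: np.ndarray, type_names: np.ndarray) -> str:
    order = np.argsort(type_names.astype(str), kind="stable")
    best = order[np.argmax(w[order])]  # ties -> alphabetically first type
    return str(type_names[best])


def assign_labels(
    weights: np.ndarray,
    type_names: Sequence[str],
    rejection_threshold: float | None = None,
    unknown_label: str = "unknown",
) -> np.ndarray:
    """Argmax label per cell, optionally rejecting low-confidence cells.

    With a rejection threshold, a cell whose largest weight falls below
    the threshold is labeled ``unknown``. Ties resolve to the
    alphabetically first type.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    type_names = np.asarray(type_names, dtype=object)
    labels = np.empty(weights.shape[0], dtype=object)
    for i, row in enumerate(weights):
        if np.all(np.isnan(row)):
            raise ValueError(f"cell at row {i} has all-NaN weights")
        if rejection_threshold is not None and np.nanmax(row) < rejection_threshold:
            labels[i] = unknown_label
        else:
            labels[i] = _argmax_label(row, type_names)
    return labels


def build_signature(
    reference: CountMatrix,
    n_hvgs: int = 2000,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> SignatureMatrix:
    """Reference counts -> filtered, normalized, HVG-restricted pseudo-bulk.

    The signature is cut down to the ``n_hvgs`` genes most variable
    across the C cell type profiles, which keeps its condition number
    small and concentrates it on type-discriminating genes.
    """
    if reference.labels is None:
        raise ValueError("reference must carry per-cell type labels")
    ref = preprocess.filter_cells_genes(reference, min_genes_per_cell, min_cells_per_gene)
    nm = preprocess.lognormalize(ref)
    H_full = preprocess.build_pseudobulk(nm)
    hvg_idx = preprocess.select_hvgs(H_full, n=n_hvgs)
    H = H_full.subset_genes(hvg_idx)
    logger.info(
        "signature: %d genes x %d types, condition number %.3g",
        H.values.shape[0], H.n_types, H.condition_number(),
    )
    return H


def annotate(
    reference: CountMatrix,
    query: CountMatrix,
    method: Literal["cp", "rpc"] = "cp",
    n_hvgs: int = 2000,
    rejection_threshold: float | None = None,
    sum_constraint: Literal["eq", "le"] = "eq",
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> AnnotationResult:
    """End-to-end annotation of unlabeled query cells against a labeled reference.

    Pipeline: filter both assays, log-normalize, build the pseudo-bulk
    signature on 2000 reference HVGs, align genes with the query, fit CP
    or RPC per cell (cells are independent), and argmax-assign labels.
    """
    method = method.lower()
    if method not in ("cp", "rpc"):
        raise ValueError(f"unknown annotation method {method!r}")
    H = build_signature(reference, n_hvgs, min_genes_per_cell, min_cells_per_gene)
    q = preprocess.filter_cells_genes(query, min_genes_per_cell, min_cells_per_gene)
    qn = preprocess.lognormalize(q)
    H_al, q_al = align_genes(H, qn)

    n = q_al.n_cells
    C = H_al.n_types
    weights = np.empty((n, C))
    resid = np.empty(n)
    A = H_al.values
    if method == "cp":
        Q = A.T @ A
        Cmat = A.T @ q_al.values  # C x cells
        for j in range(n):
            w = _solve_simplex_qp(Q, Cmat[:, j]) if sum_constraint == "eq" else fit_cp(
                q_al.values[:, j], H_al, sum_constraint
            ).weights
            weights[j] = w
            resid[j] = np.linalg.norm(q_al.values[:, j] - A @ w)
    else:
        X = np.column_stack([np.ones(A.shape[0]), A])
        for j in range(n):
            beta = _huber_irls(X, q_al.values[:, j])
            weights[j] = beta[1:]
            resid[j] = np.linalg.norm(q_al.values[:, j] - X @ beta)

    labels = assign_labels(weights, H_al.type_names, rejection_threshold)
    return AnnotationResult(
        cell_ids=q_al.cell_ids.copy(),
        type_names=H_al.type_names.copy(),
        weights=weights,
        labels=labels,
        residual_norms=resid,
        method=method,
        genes_used=A.shape[0],
    )
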