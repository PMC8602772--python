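"""Shared in-memory containers.

All matrices are genes x cells, the orientation in which signature-based
deconvolution is written (each column of the signature matrix H is a cell
type profile b_c, each query column y is one cell).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if ids.ndim != 1:
        raise ValueError(f"{what} identifiers must be one-dimensional")
    if len(set(ids)) != ids.size:
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Nonnegative integer counts, genes x cells, with identifiers.

    ``labels`` holds the per-cell type annotation when the matrix is a
    labeled reference; it is ``None`` for an unannotated query.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        g, c = self.values.shape
        if self.gene_ids.size != g:
            raise ValueError(f"{self.gene_ids.size} gene ids for {g} rows")
        if self.cell_ids.size != c:
            raise ValueError(f"{self.cell_ids.size} cell ids for {c} columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != c:
                raise ValueError("one label per cell required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        labels = None if self.labels is None else self.labels[idx]
        return replace(
            self, values=self.values[:, idx], cell_ids=self.cell_ids[idx], labels=labels
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells (natural log1p scale)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray | None = None
    size_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "NormalizedMatrix":
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])


@dataclass
class SignatureMatrix:
    """Cell type signature H: genes x C mean profiles (columns b_c)."""

    values: np.ndarray
    gene_ids: np.ndarray
    type_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.type_names = np.asarray(self.type_names, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("signature must be 2-D")
        if self.type_names.size < 1:
            raise ValueError("signature needs at least one cell type column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature contains non-finite entries")

    @property
    def n_types(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "SignatureMatrix":
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])

    def drop_types(self, names: Sequence[str]) -> "SignatureMatrix":
        keep = np.array([t not in set(names) for t in self.type_names])
        if keep.sum() == 0:
            raise ValueError("cannot drop every cell type from the signature")
        return replace(
            self, values=self.values[:, keep], type_names=self.type_names[keep]
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))
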