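"""Readers and writers for count matrices and evaluation reports.

Counts round-trip through either a 10x-style Matrix Market triplet
directory (matrix.mtx + genes.tsv + cells.tsv + optional labels.tsv) or
a dense CSV (genes as rows). Genes-as-rows is the canonical in-memory
orientation; MTX files stored cells-as-rows are transposed on load, with
the orientation inferred from the TSV lengths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .benchmark import EvaluationReport
from .containers import CountMatrix
from .simulate import PairedSimulation

__all__ = [
    "DatasetBundle",
    "read_counts",
    "write_counts",
    "write_paired",
    "write_report",
]


@dataclass
class DatasetBundle:
    counts: CountMatrix
    source: str
    format: str
    checksum: str


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def _read_tsv_column(path: Path) -> np.ndarray:
    with open(path) as fh:
        return np.array([line.rstrip("\n").split("\t")[0] for line in fh if line.strip()],
                        dtype=object)


def _to_integer(values: np.ndarray) -> np.ndarray:
    rounded = np.rint(values)
    if np.max(np.abs(values - rounded)) > 1e-9:
        raise ValueError("count matrix contains non-integer entries")
    if rounded.min() < 0:
        raise ValueError("count matrix contains negative entries")
    return rounded.astype(np.int64)


def _attach_labels(path: Path, cell_ids: np.ndarray) -> np.ndarray | None:
    labels_path = path / "labels.tsv"
    if not labels_path.exists():
        return None
    table = pd.read_csv(labels_path, sep="\t", header=None, names=["cell_id", "label"],
                        dtype=str)
    mapping = dict(zip(table["cell_id"], table["label"]))
    unknown = set(table["cell_id"]) - set(cell_ids)
    if unknown:
        raise ValueError(f"labels.tsv names unknown cell id(s): {sorted(unknown)[:5]}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"labels.tsv is missing cell id(s): {missing[:5]}")
    return np.array([mapping[c] for c in cell_ids], dtype=object)


def read_counts(path: str | Path, format: str | None = None) -> DatasetBundle:
    """Load a count matrix from an MTX triplet directory or a dense CSV."""
    path = Path(path)
    if format is None:
        format = "mtx_dir" if path.is_dir() else "csv"
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"{mtx} not found")
        values = spio.mmread(mtx)
        if sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        genes = _read_tsv_column(path / "genes.tsv")
        cells = _read_tsv_column(path / "cells.tsv")
        if values.shape == (genes.size, cells.size):
            pass
        elif values.shape == (cells.size, genes.size):
            values = values.T
        else:
            raise ValueError(
                f"matrix shape {values.shape} inconsistent with "
                f"{genes.size} genes / {cells.size} cells"
            )
        labels = _attach_labels(path, cells)
        counts = CountMatrix(_to_integer(values), genes, cells, labels)
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        counts = CountMatrix(
            _to_integer(df.to_numpy(dtype=float)),
            np.array(df.index, dtype=object),
            np.array(df.columns, dtype=object),
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return DatasetBundle(
        counts=counts, source=str(path), format=format, checksum=_checksum(counts.values)
    )


def write_counts(m: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    """Write counts as an MTX triplet directory or dense CSV."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(m.values))
        (path / "genes.tsv").write_text("\n".join(map(str, m.gene_ids)) + "\n")
        (path / "cells.tsv").write_text("\n".join(map(str, m.cell_ids)) + "\n")
        if m.labels is not None:
            with open(path / "labels.tsv", "w") as fh:
                for cid, lab in zip(m.cell_ids, m.labels):
                    fh.write(f"{cid}\t{lab}\n")
    elif format == "csv":
        pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_paired(pair: PairedSimulation, out_dir: str | Path) -> None:
    """Write a paired simulation as true/ and raw/ MTX directories."""
    out_dir = Path(out_dir)
    write_counts(pair.true_assay, out_dir / "true")
    write_counts(pair.raw_assay, out_dir / "raw")


def write_report(report: EvaluationReport, out_dir: str | Path) -> dict[str, Path]:
    """Write report.csv (long form), report.json and provenance.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "report.csv"
    json_path = out_dir / "report.json"
    prov_path = out_dir / "provenance.json"
    report.table.to_csv(csv_path, index=False, float_format="%.17g")
    json_path.write_text(
        json.dumps(report.table.to_dict(orient="records"), indent=2, default=str) + "\n"
    )

    def _jsonable(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return str(obj)

    prov_path.write_text(json.dumps(report.provenance, indent=2, default=_jsonable) + "\n")
    return {"csv": csv_path, "json": json_path, "provenance": prov_path}
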