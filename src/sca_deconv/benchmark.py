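"""Evaluation schemes over simulated paired assays.

Every scheme reduces to the same template: build a labeled reference and
an unlabeled query, annotate with one or more methods, and score the
predictions against the simulation truth. The inter-dataset scheme is
the workhorse: the dropout-free true assay is the reference and
the dropout-masked raw assay is the query.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .annotate import annotate
from .containers import CountMatrix
from .preprocess import downsample_features
from .simulate import PairedSimulation, SimulationSpec, make_design_suite, simulate_paired

__all__ = [
    "EvaluationReport",
    "run_cv5",
    "run_inter",
    "run_de_sweep",
    "run_class_sweep",
    "run_rare",
    "run_leaveout",
    "run_feature_downsample",
]

METRIC_COLUMNS = ["accuracy", "ari", "homogeneity", "completeness", "v_measure"]


@dataclass
class EvaluationReport:
    """Long-form metric table plus the provenance needed to reproduce it."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def mean_metrics(self, by: Sequence[str] = ("method",)) -> pd.DataFrame:
        return self.table.groupby(list(by))[METRIC_COLUMNS].agg(["mean", "std"])


def _spec_hash(spec: SimulationSpec) -> str:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(schema: str, seeds, extra: dict | None = None) -> dict:
    from . import __version__

    prov = {"scheme": schema, "seeds": list(np.asarray(seeds).tolist()), "version": __version__}
    if extra:
        prov.update(extra)
    return prov


def _score_row(truth, predicted, **context) -> dict:
    bundle = _metrics.evaluate(truth, predicted)
    row = dict(context)
    row.update({k: getattr(bundle, k) for k in METRIC_COLUMNS})
    return row


def run_inter(
    pair: PairedSimulation,
    methods: Sequence[str] = ("cp", "rpc"),
    n_hvgs: int = 2000,
    min_genes_per_cell: int = 200,
    **context,
) -> EvaluationReport:
    """True assay (labeled) -> raw assay prediction, scored per method."""
    if pair.true_assay.values.shape != pair.raw_assay.values.shape:
        raise ValueError("paired assays must share dimensions")
    rows = []
    per_type: dict[str, pd.Series] = {}
    for method in methods:
        query = CountMatrix(
            pair.raw_assay.values,
            pair.raw_assay.gene_ids,
            pair.raw_assay.cell_ids,
            labels=None,
        )
        result = annotate(
            pair.true_assay, query, method=method, n_hvgs=n_hvgs,
            min_genes_per_cell=min_genes_per_cell,
        )
        kept = pd.Index(pair.raw_assay.cell_ids).get_indexer(result.cell_ids)
        truth = pair.labels[kept]
        rows.append(
            _score_row(
                truth, result.labels, method=method, seed=pair.spec.seed, **context
            )
        )
        per_type[method] = _metrics.per_type_accuracy(truth, result.labels)
    report = EvaluationReport(
        pd.DataFrame(rows),
        _provenance("inter", [pair.spec.seed], {"spec_hash": _spec_hash(pair.spec)}),
    )
    report.provenance["per_type_accuracy"] = {
        m: {str(k): v for k, v in s.items()} for m, s in per_type.items()
    }
    return report


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Per-type round-robin assignment of shuffled cells to k folds."""
    rng = np.random.default_rng(seed)
    fold = np.empty(labels.size, dtype=int)
    for t in sorted(set(labels)):
        idx = np.flatnonzero(labels == t)
        if idx.size < k:
            import warnings

            warnings.warn(f"cell type {t!r} has fewer than {k} cells; folds will miss it")
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def run_cv5(
    data: CountMatrix,
    methods: Sequence[str] = ("cp", "rpc"),
    seed: int = 0,
    n_folds: int = 5,
    n_hvgs: int = 2000,
    min_genes_per_cell: int = 200,
) -> EvaluationReport:
    """Stratified k-fold cross validation: k-1 folds reference, 1 fold query."""
    if data.labels is None:
        raise ValueError("cross validation requires a labeled dataset")
    if data.n_cells < n_folds:
        raise ValueError(f"need at least {n_folds} cells for {n_folds}-fold CV")
    fold = _stratified_folds(data.labels, n_folds, seed)
    rows = []
    for f in range(n_folds):
        ref = data.subset_cells(np.flatnonzero(fold != f))
        qry_idx = np.flatnonzero(fold == f)
        qry = data.subset_cells(qry_idx)
        truth_all = qry.labels
        query = CountMatrix(qry.values, qry.gene_ids, qry.cell_ids, labels=None)
        for method in methods:
            result = annotate(
                ref, query, method=method, n_hvgs=n_hvgs,
                min_genes_per_cell=min_genes_per_cell,
            )
            kept = pd.Index(qry.cell_ids).get_indexer(result.cell_ids)
            rows.append(
                _score_row(
                    truth_all[kept], result.labels, method=method, fold=f, seed=seed
                )
            )
    return EvaluationReport(pd.DataFrame(rows), _provenance("cv5", [seed]))


def run_de_sweep(
    methods: Sequence[str] = ("cp", "rpc"),
    seeds: Sequence[int] | None = None,
    n_hvgs: int = 2000,
    levels: Sequence[str] | None = None,
) -> EvaluationReport:
    """Inter-dataset prediction across the four DE-factor scale levels."""
    specs = make_design_suite("de_sweep", seeds)
    level_names = ["low", "low_moderate", "moderate", "high"]
    n_seeds = len(specs) // 4
    rows = []
    for i, spec in enumerate(specs):
        level = level_names[i // n_seeds]
        if levels is not None and level not in levels:
            continue
        rep = run_inter(simulate_paired(spec), methods, n_hvgs, de_scale=level)
        rows.append(rep.table)
    return EvaluationReport(
        pd.concat(rows, ignore_index=True),
        _provenance("de_sweep", sorted({s.seed for s in specs})),
    )


def run_class_sweep(
    methods: Sequence[str] = ("cp", "rpc"),
    seeds: Sequence[int] = (1,),
    class_numbers: Sequence[int] = (10, 20),
    n_hvgs: int = 2000,
) -> EvaluationReport:
    """Inter-dataset prediction with growing numbers of cell type classes.

    The full design runs N up to 50 over 10,000 cells; the default here
    covers N <= 20 (the larger settings are extended-runtime options).
    """
    rows = []
    for s in seeds:
        for spec in make_design_suite("class_sweep", [s]):
            if spec.n_groups not in set(class_numbers):
                continue
            rep = run_inter(simulate_paired(spec), methods, n_hvgs, n_classes=spec.n_groups)
            rows.append(rep.table)
    return EvaluationReport(
        pd.concat(rows, ignore_index=True), _provenance("class_sweep", list(seeds))
    )


def run_rare(
    methods: Sequence[str] = ("cp", "rpc"),
    seeds: Sequence[int] | None = None,
    n_hvgs: int = 2000,
) -> EvaluationReport:
    """Rare-population design: per-group recall, groups ordered by proportion."""
    specs = make_design_suite("rare", seeds)
    rows = []
    per_type_rows = []
    for spec in specs:
        pair = simulate_paired(spec)
        rep = run_inter(pair, methods, n_hvgs)
        rows.append(rep.table)
        for method, accs in rep.provenance["per_type_accuracy"].items():
            for group, acc in accs.items():
                per_type_rows.append(
                    {"method": method, "seed": spec.seed, "group": group, "recall": acc}
                )
    per_type = pd.DataFrame(per_type_rows)
    # order groups by their designed proportion, descending
    names = specs[0].resolved_group_names()
    props = dict(zip(names, specs[0].group_proportions))
    per_type["proportion"] = per_type["group"].map(props)
    per_type = per_type.sort_values(
        ["method", "proportion"], ascending=[True, False]
    ).reset_index(drop=True)
    report = EvaluationReport(
        pd.concat(rows, ignore_index=True),
        _provenance("rare", sorted({s.seed for s in specs})),
    )
    report.provenance["per_type_table"] = per_type
    return report


def run_leaveout(
    pair: PairedSimulation,
    methods_with_rejection: Mapping[str, float],
    k: int = 1,
    n_hvgs: int = 2000,
    min_genes_per_cell: int = 200,
) -> EvaluationReport:
    """Leave-out-k unknown-type detection.

    For every combination of k cell types, those types' cells are removed
    from the reference (their signatures vanish) while the query stays
    intact. Reported per combination: metrics over query cells whose true
    type remains in the reference, and the fraction of left-out-type
    cells labeled ``unknown``.
    """
    types = sorted(set(pair.labels))
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if k >= len(types):
        raise ValueError("cannot leave out every cell type")
    rows = []
    for combo in combinations(types, k):
        held = set(combo)
        ref_keep = np.array([lab not in held for lab in pair.labels])
        query = CountMatrix(
            pair.raw_assay.values, pair.raw_assay.gene_ids, pair.raw_assay.cell_ids
        )
        for method, threshold in methods_with_rejection.items():
            result = annotate(
                pair.true_assay.subset_cells(np.flatnonzero(ref_keep)),
                query,
                method=method,
                n_hvgs=n_hvgs,
                rejection_threshold=threshold,
                min_genes_per_cell=min_genes_per_cell,
            )
            kept = pd.Index(pair.raw_assay.cell_ids).get_indexer(result.cell_ids)
            truth = pair.labels[kept]
            in_ref = np.array([lab not in held for lab in truth])
            held_mask = ~in_ref
            unknown_acc = (
                float((result.labels[held_mask] == "unknown").mean())
                if held_mask.any()
                else float("nan")
            )
            degenerate = bool(np.all(result.labels[in_ref] == "unknown"))
            if degenerate:
                row = dict.fromkeys(METRIC_COLUMNS, 0.0)
            else:
                bundle = _metrics.evaluate(truth, result.labels, mask=in_ref)
                row = {k2: getattr(bundle, k2) for k2 in METRIC_COLUMNS}
            row.update(
                method=method,
                left_out="+".join(combo),
                k=k,
                unknown_accuracy=unknown_acc,
                degenerate=degenerate,
                seed=pair.spec.seed,
            )
            rows.append(row)
    return EvaluationReport(
        pd.DataFrame(rows),
        _provenance("leaveout", [pair.spec.seed], {"k": k}),
    )


def run_feature_downsample(
    pair: PairedSimulation,
    methods: Sequence[str] = ("cp", "rpc"),
    sizes: Sequence[int] = (5000, 10_000, 15_000),
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    n_hvgs: int = 2000,
    min_genes_per_cell: int = 200,
) -> EvaluationReport:
    """Robustness to random gene downsampling of the query."""
    rows = []
    for size in sizes:
        for s in seeds:
            if size > pair.raw_assay.n_genes:
                raise ValueError(
                    f"downsample size {size} exceeds {pair.raw_assay.n_genes} genes"
                )
            query_counts = downsample_features(pair.raw_assay, size, seed=s)
            query = CountMatrix(
                query_counts.values, query_counts.gene_ids, query_counts.cell_ids
            )
            for method in methods:
                result = annotate(
                    pair.true_assay, query, method=method, n_hvgs=n_hvgs,
                    min_genes_per_cell=min_genes_per_cell,
                )
                kept = pd.Index(pair.raw_assay.cell_ids).get_indexer(result.cell_ids)
                rows.append(
                    pd.DataFrame(
                        [
                            _score_row(
                                pair.labels[kept],
                                result.labels,
                                method=method,
                                n_features=size,
                                subsample_seed=s,
                                seed=pair.spec.seed,
                            )
                        ]
                    )
                )
    return EvaluationReport(
        pd.concat(rows, ignore_index=True),
        _provenance("feature_downsample", list(seeds), {"sizes": list(sizes)}),
    )
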