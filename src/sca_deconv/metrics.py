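"""Classification agreement metrics for predicted vs. true cell labels.

Overall accuracy, Hubert-Arabie adjusted Rand index, and the V-measure
(harmonic mean of entropy-based homogeneity and completeness), plus
per-type recall and the confusion table. All are computed directly from
the truth/prediction contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricBundle",
    "overall_accuracy",
    "adjusted_rand_index",
    "v_measure",
    "per_type_accuracy",
    "confusion_table",
    "evaluate",
]


def _as_pair(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if t.size != p.size:
        raise ValueError("truth and prediction must have equal length")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        t, p = t[m], p[m]
    if t.size == 0:
        raise ValueError("no cells left to evaluate")
    return t, p


def _contingency(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    t_codes, _ = pd.factorize(t, sort=True)
    p_codes, _ = pd.factorize(p, sort=True)
    table = np.zeros((t_codes.max() + 1, p_codes.max() + 1), dtype=np.int64)
    np.add.at(table, (t_codes, p_codes), 1)
    return table


def overall_accuracy(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    t, p = _as_pair(truth, predicted, mask)
    return float((t == p).mean())


def adjusted_rand_index(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> float:
    """Chance-adjusted pair-counting agreement between two partitions."""
    t, p = _as_pair(truth, predicted, mask)
    if t.size < 2:
        raise ValueError("ARI requires at least two cells")
    table = _contingency(t, p)
    n = t.size

    def comb2(x: np.ndarray) -> np.ndarray:
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(np.array(n))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> tuple[float, float, float]:
    """(homogeneity, completeness, V) with natural-log entropies, beta = 1."""
    t, p = _as_pair(truth, predicted, mask)
    table = _contingency(t, p).astype(float)
    n = table.sum()
    h_truth = _entropy(table.sum(axis=1))
    h_pred = _entropy(table.sum(axis=0))

    # conditional entropies from the joint table
    h_t_given_p = 0.0
    for col in table.T:
        if col.sum() > 0:
            h_t_given_p += (col.sum() / n) * _entropy(col)
    h_p_given_t = 0.0
    for row in table:
        if row.sum() > 0:
            h_p_given_t += (row.sum() / n) * _entropy(row)

    homogeneity = 1.0 if h_truth == 0 else 1.0 - h_t_given_p / h_truth
    completeness = 1.0 if h_pred == 0 else 1.0 - h_p_given_t / h_pred
    if homogeneity + completeness == 0:
        v = 0.0
    else:
        v = 2.0 * homogeneity * completeness / (homogeneity + completeness)
    return homogeneity, completeness, v


def per_type_accuracy(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> pd.Series:
    """Recall per true type: correct within type / type size."""
    t, p = _as_pair(truth, predicted, mask)
    out = {}
    for name in sorted(set(t)):
        m = t == name
        out[name] = float((p[m] == name).mean())
    return pd.Series(out, name="per_type_accuracy")


def confusion_table(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> pd.DataFrame:
    """True types (rows) x predicted labels (columns) cell counts."""
    t, p = _as_pair(truth, predicted, mask)
    return pd.crosstab(
        pd.Series(t, name="truth"), pd.Series(p, name="predicted")
    )


@dataclass
class MetricBundle:
    """All evaluation criteria for one truth/prediction pair."""

    accuracy: float
    ari: float
    homogeneity: float
    completeness: float
    v_measure: float
    per_type: pd.Series
    confusion: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "v_measure": self.v_measure,
            "per_type_accuracy": {str(k): v for k, v in self.per_type.items()},
        }


def evaluate(
    truth: Sequence[str], predicted: Sequence[str], mask: Sequence[bool] | None = None
) -> MetricBundle:
    """Compute every criterion at once."""
    h, c, v = v_measure(truth, predicted, mask)
    return MetricBundle(
        accuracy=overall_accuracy(truth, predicted, mask),
        ari=adjusted_rand_index(truth, predicted, mask),
        homogeneity=h,
        completeness=c,
        v_measure=v,
        per_type=per_type_accuracy(truth, predicted, mask),
        confusion=confusion_table(truth, predicted, mask),
    )
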