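"""Filtering, normalization, pseudo-bulk, HVG, markers, downsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sca_deconv import (
    CountMatrix,
    NormalizedMatrix,
    build_pseudobulk,
    downsample_features,
    filter_cells_genes,
    lognormalize,
    select_hvgs,
    wilcoxon_markers,
)
from tests.conftest import random_counts


def cm(values, labels=None):
    values = np.asarray(values)
    g, c = values.shape
    return CountMatrix(
        values,
        np.array([f"g{i}" for i in range(g)], dtype=object),
        np.array([f"c{j}" for j in range(c)], dtype=object),
        labels,
    )


class TestFilter:
    def test_toy_enumeration(self):
        # cell c4 detects 1 gene; gene g4 appears in 1 cell (and dies with c4)
        values = np.array(
            [
                [5, 3, 2, 1, 0],
                [1, 1, 1, 0, 0],
                [2, 0, 3, 1, 0],
                [0, 0, 0, 0, 4],
                [1, 2, 0, 1, 0],
            ]
        )
        out = filter_cells_genes(cm(values), min_genes_per_cell=2, min_cells_per_gene=2)
        assert list(out.cell_ids) == ["c0", "c1", "c2", "c3"]
        assert list(out.gene_ids) == ["g0", "g1", "g2", "g4"]

    def test_fixed_point(self, rng):
        m = cm(rng.integers(1, 5, size=(300, 10)))
        out = filter_cells_genes(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert list(out.gene_ids) == list(m.gene_ids)

    def test_gene_filter_applied_after_cell_filter(self):
        # gene g0 is expressed in 2 cells, but one of them is removed first
        values = np.array([[1, 1, 0, 0], [0, 3, 2, 2], [0, 1, 1, 1]])
        out = filter_cells_genes(cm(values), min_genes_per_cell=2, min_cells_per_gene=2)
        assert "c0" not in out.cell_ids
        assert "g0" not in out.gene_ids

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="all cells removed"):
            filter_cells_genes(cm(np.zeros((5, 5), dtype=int)))
        with pytest.raises(ValueError, match="empty"):
            filter_cells_genes(cm(np.zeros((0, 0), dtype=int)))

    def test_labels_subset(self):
        values = np.array([[2, 2, 0], [1, 1, 0], [3, 0, 1]])
        m = cm(values, labels=np.array(["a", "b", "c"], dtype=object))
        out = filter_cells_genes(m, min_genes_per_cell=2, min_cells_per_gene=1)
        assert list(out.labels) == ["a", "b"]


class TestLognormalize:
    def test_single_count_closed_form(self):
        m = cm([[3], [0]])
        nm = lognormalize(m)
        assert nm.values[0, 0] == pytest.approx(np.log(1 + 1e4), rel=1e-12)
        assert nm.values[1, 0] == 0.0

    def test_zero_cell_stays_zero(self):
        nm = lognormalize(cm([[1, 0], [2, 0]]))
        assert np.all(nm.values[:, 1] == 0)
        assert np.all(np.isfinite(nm.values))

    def test_elementwise_oracle(self, rng):
        m = random_counts(rng, n_genes=10, n_cells=4)
        nm = lognormalize(m, size_factor=1e4)
        totals = m.values.sum(axis=0)
        for g in range(10):
            for j in range(4):
                expected = np.log(1 + 1e4 * m.values[g, j] / totals[j])
                assert nm.values[g, j] == pytest.approx(expected, abs=1e-12)

    def test_negative_size_factor(self):
        with pytest.raises(ValueError):
            lognormalize(cm([[1]]), size_factor=-1)


class TestPseudobulk:
    def test_hand_means(self):
        values = np.arange(24).reshape(4, 6).astype(float)
        nm = NormalizedMatrix(
            values,
            np.array([f"g{i}" for i in range(4)], dtype=object),
            np.array([f"c{j}" for j in range(6)], dtype=object),
        )
        labels = np.array(["B", "A", "B", "A", "A", "B"], dtype=object)
        H = build_pseudobulk(nm, labels)
        assert list(H.type_names) == ["A", "B"]
        np.testing.assert_allclose(H.values[:, 0], values[:, [1, 3, 4]].mean(axis=1))
        np.testing.assert_allclose(H.values[:, 1], values[:, [0, 2, 5]].mean(axis=1))

    def test_single_and_duplicate_cells(self):
        values = np.array([[1.0, 2.0, 2.0], [4.0, 5.0, 5.0]])
        nm = NormalizedMatrix(
            values,
            np.array(["g0", "g1"], dtype=object),
            np.array(["c0", "c1", "c2"], dtype=object),
        )
        H = build_pseudobulk(nm, np.array(["t1", "t2", "t2"], dtype=object))
        np.testing.assert_allclose(H.values[:, 0], values[:, 0])  # mean of one
        np.testing.assert_allclose(H.values[:, 1], values[:, 1])  # idempotent mean

    def test_commutes_with_cell_permutation(self, rng):
        m = random_counts(rng, n_genes=20, n_cells=15)
        labels = rng.choice(["x", "y", "z"], size=15).astype(object)
        nm = lognormalize(m)
        H1 = build_pseudobulk(nm, labels)
        perm = rng.permutation(15)
        nm2 = NormalizedMatrix(nm.values[:, perm], nm.gene_ids, nm.cell_ids[perm])
        H2 = build_pseudobulk(nm2, labels[perm])
        np.testing.assert_allclose(H1.values, H2.values)


class TestSelectHvgs:
    def _nm(self, values):
        g = values.shape[0]
        return NormalizedMatrix(
            values,
            np.array([f"g{i:03d}" for i in range(g)], dtype=object),
            np.array([f"c{j}" for j in range(values.shape[1])], dtype=object),
        )

    def test_saturation_returns_all_genes(self, rng):
        nm = self._nm(rng.random((15, 6)))
        idx = select_hvgs(nm, n=100)
        assert sorted(idx) == list(range(15))

    def test_invalid_n(self, rng):
        with pytest.raises(ValueError):
            select_hvgs(self._nm(rng.random((5, 4))), n=0)

    def test_planted_signal_ranks_high(self):
        """A single group-shifted gene lands in the top 1% over 5 seeds."""
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            base = r.uniform(1.0, 4.0, size=200)  # spread of expression levels
            values = np.abs(base[:, None] + r.normal(0, 0.3, size=(200, 80)))
            values[37, 40:] += 2.5  # one gene separates two halves
            idx = select_hvgs(self._nm(values), n=2)
            hits += 37 in idx
        assert hits == 5

    def test_invariant_to_cell_order(self, rng):
        values = rng.gamma(2.0, 1.0, size=(100, 30))
        nm = self._nm(values)
        perm = rng.permutation(30)
        nm2 = self._nm(values[:, perm])
        np.testing.assert_array_equal(select_hvgs(nm, 10), select_hvgs(nm2, 10))


def exact_ranksum_pvalue(a, b):
    """Two-sided rank-sum p by full enumeration (tie-free, small samples)."""
    combined = np.concatenate([a, b])
    ranks = pd.Series(combined).rank().to_numpy()
    n = len(a)
    observed = ranks[:n].sum()
    sums = [
        sum(ranks[list(pick)])
        for pick in itertools.combinations(range(len(combined)), n)
    ]
    mean = np.mean(sums)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-9 for s in sums)
    return extreme / len(sums)


class TestWilcoxonMarkers:
    def _dataset(self, shift):
        r = np.random.default_rng(5)
        values = r.gamma(2.0, 1.0, size=(30, 16))
        values[3, :8] += shift  # candidate marker for group "one"
        nm = NormalizedMatrix(
            values,
            np.array([f"g{i}" for i in range(30)], dtype=object),
            np.array([f"c{j}" for j in range(16)], dtype=object),
        )
        labels = np.array(["one"] * 8 + ["two"] * 8, dtype=object)
        return nm, labels

    def test_shifted_gene_is_top_marker_with_exact_p(self):
        nm, labels = self._dataset(shift=4.0)
        table = wilcoxon_markers(nm, labels, top_k=5, min_pct=0.1, logfc_threshold=0.1)
        top = table[table.cell_type == "one"].iloc[0]
        assert top.gene == "g3"
        a = nm.values[3, :8]
        b = nm.values[3, 8:]
        assert top.p_value == pytest.approx(exact_ranksum_pvalue(a, b), abs=1e-12)

    def test_null_gene_never_marker(self):
        nm, labels = self._dataset(shift=0.0)
        table = wilcoxon_markers(nm, labels, top_k=30)
        # identically distributed genes fail the logFC filter or are not ranked first
        assert (table.p_value > 1e-4).all()

    def test_small_type_skipped_with_warning(self):
        nm, labels = self._dataset(shift=4.0)
        labels = labels.copy()
        labels[:2] = "tiny"
        labels[2:8] = "one"
        with pytest.warns(UserWarning, match="tiny"):
            table = wilcoxon_markers(nm, labels, min_pct=0.1, logfc_threshold=0.1)
        assert "tiny" not in set(table.cell_type)

    def test_requires_two_types(self):
        nm, labels = self._dataset(shift=1.0)
        with pytest.raises(ValueError):
            wilcoxon_markers(nm, np.full(16, "only", dtype=object))


class TestDownsampleFeatures:
    def test_identity_when_keeping_all(self, rng):
        m = random_counts(rng, n_genes=40, n_cells=8)
        out = downsample_features(m, 40, seed=1)
        np.testing.assert_array_equal(out.values, m.values)

    def test_stratification_on_bimodal_totals(self):
        r = np.random.default_rng(3)
        low = r.poisson(2, size=(100, 20))
        high = r.poisson(200, size=(100, 20))
        m = cm(np.vstack([low, high]))
        out = downsample_features(m, 100, seed=9)
        kept_low = sum(1 for g in out.gene_ids if int(g[1:]) < 100)
        assert abs(kept_low - 50) <= 1

    def test_deterministic_and_validated(self, rng):
        m = random_counts(rng, n_genes=40, n_cells=8)
        a = downsample_features(m, 10, seed=5)
        b = downsample_features(m, 10, seed=5)
        assert list(a.gene_ids) == list(b.gene_ids)
        with pytest.raises(ValueError):
            downsample_features(m, 0)
        with pytest.raises(ValueError):
            downsample_features(m, 41)


def test_filter_normalize_filter_idempotent(rng):
    m = random_counts(rng, n_genes=300, n_cells=12, lam=1.2)
    once = filter_cells_genes(m, min_genes_per_cell=50, min_cells_per_gene=3)
    again = filter_cells_genes(once, min_genes_per_cell=50, min_cells_per_gene=3)
    np.testing.assert_array_equal(once.values, again.values)
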