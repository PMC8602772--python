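# sca-deconv

Reference-based cell type annotation for scRNA-seq by repurposed bulk
deconvolution, with a gamma-Poisson paired-assay simulator and an
evaluation harness.

## What it does

Given an annotated reference count matrix and an unlabeled query, the
package collapses the reference into a pseudo-bulk **signature matrix**
H — column *b<sub>c</sub>* is the mean log-normalized profile of cell
type *c*, restricted to the 2000 genes most variable across types — and
models each query cell's profile **y** as a weighted combination of the
type profiles,

&nbsp;&nbsp;&nbsp;&nbsp;y = Σ<sub>c</sub> w<sub>c</sub> b<sub>c</sub> + ε,

assigning the type with the largest estimated weight. Two estimators are
provided:

* **CP** (constrained projection): w = argmin ‖y − Hw‖² subject to
  w ≥ 0, Σw = 1, solved per cell by quadratic programming.
* **RPC** (robust partial correlations): Huber-loss robust linear
  regression of y on H (IRLS, intercept included), insensitive to
  outlier genes such as dropout-induced zeros.

The package is aimed at people benchmarking or deploying annotation
methods: it ships the full benchmarking apparatus — a Splatter-style
gamma-Poisson simulator that emits paired *true* (dropout-free) and
*raw* (dropout-masked) assays, preprocessing (filtering, log
normalization, pseudo-bulk, HVG and Wilcoxon marker selection, feature
downsampling), evaluation metrics (overall accuracy, adjusted Rand
index, V-measure, per-type recall), and scheme runners (5-fold CV,
inter-dataset prediction, DE-scale / class-number / rare-population
sweeps, leave-out-k unknown detection, feature-downsampling
robustness). See `docs/methods.md` for the model and all numerical
choices.

## Worked example

Simulate the base paired design (4000 genes × 2000 cells, five groups at
10/30/30/10/20%, logistic dropout with shape −0.5 and midpoint 1), use
the dropout-free assay as the labeled reference and the dropout-masked
assay as the query, and score both annotators against the simulation
truth:

```python
from sca_deconv import SimulationSpec, simulate_paired, run_inter

spec = SimulationSpec(
    n_genes=4000, n_cells=2000,
    group_proportions=(0.10, 0.30, 0.30, 0.10, 0.20),
    seed=1,
)
pair = simulate_paired(spec)
report = run_inter(pair, methods=("cp", "rpc"))
print(report.table[["method", "accuracy", "ari", "v_measure"]])
```

```
  method  accuracy  ari  v_measure
0     cp       1.0  1.0        1.0
1    rpc       1.0  1.0        1.0
```

Even with roughly half the query entries zeroed by dropout (48.1% zeros
in the raw assay versus 19.2% in the true assay at these settings), both
estimators recover every label here: the pseudo-bulk averaging on
the reference side and the per-cell fit on the query side are robust to
expression-dependent zero inflation. Accuracy is exact label agreement,
ARI the chance-adjusted pair-counting index, V-measure the harmonic mean
of homogeneity and completeness.

The same pipeline is available from the shell:

```bash
sca-deconv simulate --design base --seed 1 --out data/
sca-deconv annotate --ref data/base_000_seed1/true --query data/base_000_seed1/raw \
    --method cp --out predictions.tsv
sca-deconv metrics --truth truth.tsv --pred predictions.tsv --out metrics.json
sca-deconv benchmark --scheme de_sweep --methods cp,rpc --seed 1 --out report/
```

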