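"""Gamma-Poisson paired-assay simulator for grouped scRNA-seq counts.

The generative hierarchy follows the standard gamma-Poisson single-cell
count model with group structure:

1. gene base means  lambda_g ~ Gamma(mean_shape, rate=mean_rate)
2. per-group multiplicative DE factors: a random ``de_prob`` subset of
   genes receives f_gk = exp(de_fac_loc + de_fac_scale[k] * z_gk) with
   z_gk ~ N(0, 1); with probability ``de_down_prob`` the factor is
   inverted (down-regulation), all other genes keep f = 1
3. cell library sizes  L_j ~ LogNormal(lib_loc, lib_scale)
4. cell means  mu_gj = L_j * lambda_g f_g,group(j) / sum_g lambda_g f_g,group(j)
5. biological coefficient of variation: an inverse-chi-square trended
   over-dispersion inflates each mean through a Gamma draw
6. true counts ~ Poisson(mu''), and the *raw* assay zeroes each entry
   independently with probability logistic(dropout_shape * (log mu'' -
   dropout_mid))

Structural randomness (which genes are DE, their factor magnitudes before
scaling) is driven by ``structure_seed`` so that sweeps over
``de_fac_scale`` share the same DE gene set and differ only in magnitude;
``seed`` drives all sampling noise. By default the two coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import CountMatrix

__all__ = ["SimulationSpec", "PairedSimulation", "simulate_paired", "make_design_suite"]

#: group proportions of the base paired-simulation design
BASE_PROPORTIONS = (0.10, 0.30, 0.30, 0.10, 0.20)

#: descending proportions of the rare-population design (9 groups)
RARE_PROPORTIONS = (
    0.5125, 0.2470, 0.1185, 0.0650, 0.0270, 0.0170, 0.0085, 0.0030, 0.0015,
)

#: log-normal DE factor scales per group, from easiest to hardest separation
DE_SCALE_LEVELS = {
    "low": (0.1, 0.3, 0.1, 0.3, 0.2),
    "low_moderate": (0.3, 0.5, 0.3, 0.5, 0.4),
    "moderate": (0.5, 0.7, 0.5, 0.7, 0.6),
    "high": (0.7, 0.9, 0.7, 0.9, 0.8),
}


@dataclass
class SimulationSpec:
    """Parameters of one paired-assay simulation.

    Defaults mirror the common gamma-Poisson simulator conventions:
    gene-mean Gamma(shape 0.6, rate 0.3), library LogNormal(11, 0.2),
    DE probability 0.1 with location 0.1, symmetric down-regulation,
    common BCV 0.1 with 60 degrees of freedom, and the default logistic
    dropout (midpoint 1, shape -0.5).
    """

    n_genes: int
    n_cells: int
    group_proportions: Sequence[float]
    de_fac_scale: Sequence[float] = None  # type: ignore[assignment]
    seed: int = 0
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_down_prob: float = 0.5
    dropout_mid: float = 1.0
    dropout_shape: float = -0.5
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    bcv_common: float = 0.1
    bcv_df: float | None = 60.0
    structure_seed: int | None = None
    group_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.group_proportions = tuple(float(p) for p in self.group_proportions)
        if self.de_fac_scale is None:
            self.de_fac_scale = tuple(0.4 for _ in self.group_proportions)
        else:
            self.de_fac_scale = tuple(float(s) for s in self.de_fac_scale)
        self.validate()

    @property
    def n_groups(self) -> int:
        return len(self.group_proportions)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"group proportions must sum to 1, got {sum(self.group_proportions)!r}"
            )
        if any(p <= 0 for p in self.group_proportions):
            raise ValueError("group proportions must be positive")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        if len(self.de_fac_scale) != self.n_groups:
            raise ValueError(
                "need one de_fac_scale per group "
                f"({len(self.de_fac_scale)} scales, {self.n_groups} groups)"
            )
        if any(s < 0 for s in self.de_fac_scale):
            raise ValueError("de_fac_scale entries must be nonnegative")

    def group_sizes(self) -> np.ndarray:
        """Largest-remainder apportionment of cells to groups."""
        props = np.asarray(self.group_proportions)
        exact = props * self.n_cells
        sizes = np.floor(exact).astype(int)
        remainder = self.n_cells - sizes.sum()
        order = np.argsort(-(exact - sizes), kind="stable")
        sizes[order[:remainder]] += 1
        names = self.resolved_group_names()
        for k, s in enumerate(sizes):
            if s == 0:
                raise ValueError(
                    f"group {names[k]} receives zero cells at n_cells={self.n_cells}"
                )
        return sizes

    def resolved_group_names(self) -> list[str]:
        if self.group_names is not None:
            names = [str(g) for g in self.group_names]
            if len(names) != self.n_groups:
                raise ValueError("one group name per group required")
            return names
        width = len(str(self.n_groups))
        return [f"Group{str(k + 1).zfill(width)}" for k in range(self.n_groups)]


@dataclass
class PairedSimulation:
    """A true (dropout-free) assay and its dropout-masked raw copy."""

    true_assay: CountMatrix
    raw_assay: CountMatrix
    labels: np.ndarray
    de_gene_index: dict[str, dict[str, np.ndarray]]
    spec: SimulationSpec

    def __post_init__(self) -> None:
        if self.true_assay.values.shape != self.raw_assay.values.shape:
            raise ValueError("paired assays must share dimensions")


def _dropout_probability(log_mean: np.ndarray, shape: float, mid: float) -> np.ndarray:
    """Logistic dropout curve on the log-expression axis."""
    # expit(shape * (x - mid)); negative shape => dropout falls with expression
    z = shape * (log_mean - mid)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def simulate_paired(spec: SimulationSpec) -> PairedSimulation:
    """Draw one paired simulation (deterministic given the spec's seeds)."""
    spec.validate()
    sizes = spec.group_sizes()
    names = spec.resolved_group_names()
    g, n = spec.n_genes, spec.n_cells

    struct = np.random.default_rng(
        spec.seed if spec.structure_seed is None else spec.structure_seed
    )
    noise = np.random.default_rng(spec.seed)

    # --- structural draws (shared across DE-scale sweeps) ---
    base_means = struct.gamma(shape=spec.mean_shape, scale=1.0 / spec.mean_rate, size=g)
    is_de = struct.random((g, spec.n_groups)) < spec.de_prob
    z = struct.standard_normal((g, spec.n_groups))
    down = struct.random((g, spec.n_groups)) < spec.de_down_prob

    scales = np.asarray(spec.de_fac_scale)
    factors = np.exp(spec.de_fac_loc + z * scales[None, :])
    factors[down] = 1.0 / factors[down]
    factors[~is_de] = 1.0

    de_gene_index = {
        name: {
            "genes": np.flatnonzero(is_de[:, k]),
            "factors": factors[is_de[:, k], k],
        }
        for k, name in enumerate(names)
    }

    # --- sampling noise ---
    group_of = np.repeat(np.arange(spec.n_groups), sizes)
    group_of = noise.permutation(group_of)
    lib = noise.lognormal(mean=spec.lib_loc, sigma=spec.lib_scale, size=n)

    group_profiles = base_means[:, None] * factors  # genes x groups
    group_profiles /= group_profiles.sum(axis=0, keepdims=True)
    mu = group_profiles[:, group_of] * lib[None, :]

    if spec.bcv_df is not None and math.isfinite(spec.bcv_df):
        chi = noise.chisquare(spec.bcv_df, size=g) / spec.bcv_df
        with np.errstate(divide="ignore"):
            bcv = (spec.bcv_common + 1.0 / np.sqrt(mu)) * np.sqrt(1.0 / chi)[:, None]
        disp = bcv**2
        mu = noise.gamma(shape=1.0 / disp, scale=mu * disp)
    elif spec.bcv_common > 0:
        disp = spec.bcv_common**2
        mu = noise.gamma(shape=1.0 / disp, scale=mu * disp)

    true_counts = noise.poisson(mu)

    with np.errstate(divide="ignore"):
        log_mu = np.log(np.maximum(mu, np.finfo(float).tiny))
    p_drop = _dropout_probability(log_mu, spec.dropout_shape, spec.dropout_mid)
    keep = noise.random((g, n)) >= p_drop
    raw_counts = np.where(keep, true_counts, 0)

    gene_ids = np.array([f"Gene{i + 1}" for i in range(g)], dtype=object)
    cell_ids = np.array([f"Cell{j + 1}" for j in range(n)], dtype=object)
    labels = np.array([names[k] for k in group_of], dtype=object)

    true_assay = CountMatrix(true_counts, gene_ids, cell_ids, labels.copy())
    raw_assay = CountMatrix(raw_counts, gene_ids.copy(), cell_ids.copy(), labels.copy())
    return PairedSimulation(true_assay, raw_assay, labels, de_gene_index, spec)


def make_design_suite(design: str, seeds: Sequence[int] | None = None) -> list[SimulationSpec]:
    """Expand a named study design into its list of simulation specs.

    Designs
    -------
    ``base``
        4000 genes x 2000 cells, proportions 10/30/30/10/20%, one spec
        per seed.
    ``de_sweep``
        10,000 genes x 2000 cells, 5 equal groups; four DE-factor scale
        levels (low -> high), each repeated per seed; the DE gene set is
        tied to the seed so levels differ only in factor magnitude.
    ``class_sweep``
        20,000 genes x 10,000 cells, N in {10, 20, 30, 40, 50} equal
        groups per seed.
    ``rare``
        10,000 genes x 2000 cells, 9 groups with descending proportions
        51.25% ... 0.15%, defaulting to 10 seeds.
    ``scale_sweep``
        20,000 genes, 5 equal groups, total cells in {5000, ..., 50,000}.
    """
    if seeds is None:
        seeds = list(range(1, 11)) if design == "rare" else list(range(1, 6))
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")

    equal5 = tuple(1 / 5 for _ in range(5))
    specs: list[SimulationSpec] = []
    if design == "base":
        for s in seeds:
            specs.append(
                SimulationSpec(4000, 2000, BASE_PROPORTIONS, seed=s)
            )
    elif design == "de_sweep":
        for level in ("low", "low_moderate", "moderate", "high"):
            for s in seeds:
                specs.append(
                    SimulationSpec(
                        10_000,
                        2000,
                        equal5,
                        de_fac_scale=DE_SCALE_LEVELS[level],
                        seed=s,
                        structure_seed=s,
                    )
                )
    elif design == "class_sweep":
        for s in seeds:
            for n_groups in (10, 20, 30, 40, 50):
                specs.append(
                    SimulationSpec(
                        20_000,
                        10_000,
                        tuple(1 / n_groups for _ in range(n_groups)),
                        seed=s,
                    )
                )
    elif design == "rare":
        for s in seeds:
            specs.append(
                SimulationSpec(10_000, 2000, RARE_PROPORTIONS, seed=s)
            )
    elif design == "scale_sweep":
        for s in seeds:
            for n_cells in (5000, 10_000, 15_000, 20_000, 25_000, 50_000):
                specs.append(SimulationSpec(20_000, n_cells, equal5, seed=s))
    else:
        raise ValueError(f"unknown design {design!r}")
    return specs
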