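"""Labeled synthetic expression data on a subline phylogeny.

Genes are simulated by exact transition sampling of BM / OU dynamics
down the tree (no time-discretization error), then expanded into
single-cell replicates with Gaussian noise of variance gamma * sigma^2.
An optional monotone map onto a nonnegative TPM-like scale (2^x - 1,
clipped at 0) makes the generated matrices look like the expression
input the scan expects; it is the exact inverse of the log2(x + 1)
analysis transform.

A bundled 23-tip fixture tree mirrors the clade structure of the real
subline phylogeny (three phenotype clades HA-R, HA-S, LA-S among 23
single-cell-derived sublines) with arbitrary mutation-count branch
lengths; it powers tests and the simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .phylo import BACKGROUND, Phylogeny, RegimePainting, normalize_height, parse_tree

LABELS = ("neutral", "constrained", "adaptive")

# Fixture phylogeny: 23 sublines, three phenotype clades, non-ultrametric
# integer (mutation-count-like) branch lengths.
FIXTURE_NEWICK = (
    "(((((C16:20,(C11:15,(C15:10,C18:12):6):8):25,(C2:30,C5:28):10):15,"
    "((C4:18,(C22:14,C1:16):7):22,(C6:25,(C7:20,C8:22):9):12):10):12,"
    "(((C14:16,(C3:12,C10:14):6):20,(C9:26,C12:24):11):14,"
    "(C13:30,(C17:22,(C19:20,C20:18):8):10,C21:28,C23:32):9):11):0);"
)

FIXTURE_REGIMES = {
    "HA-R": ("C11", "C15", "C18", "C16"),
    "HA-S": ("C1", "C4", "C22"),
    "LA-S": ("C3", "C10", "C14"),
}


def fixture_tree(normalized: bool = True) -> Phylogeny:
    """The bundled 23-tip test phylogeny (unit height unless disabled)."""
    tree = parse_tree(FIXTURE_NEWICK)
    return normalize_height(tree) if normalized else tree


@dataclass(frozen=True)
class SimSpec:
    """One simulation condition: model kind plus generating parameters."""

    kind: str                    # "BM" | "OU1" | "OU2"
    alpha: float = 0.0
    sigma2: float = 1.0
    gamma: float = 0.1
    theta0: float = 5.0          # background optimum / BM root state
    theta1: float = 5.0          # chosen optimum (OU2 only)
    replicates: int = 8          # cells per subline
    n_genes: int = 100
    label: str = "neutral"

    def __post_init__(self) -> None:
        if self.kind not in ("BM", "OU1", "OU2"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.sigma2 <= 0 or self.gamma < 0 or self.alpha < 0:
            raise ValueError("invalid parameters")
        if self.replicates < 1 or self.n_genes < 1:
            raise ValueError("replicates and n_genes must be >= 1")


def default_grid(replicates: tuple[int, ...] = (4, 8), n_genes: int = 100) -> list[SimSpec]:
    """The default simulation grid spanning strong and weak signals.

    Adaptive conditions cross optimum gap {0.5, 1, 2} x alpha {2, 10, 50}
    x noise gamma {0.01, 0.1, 0.5} x replicates; each adaptive condition
    is matched by a neutral condition at the same noise level.
    """
    specs: list[SimSpec] = []
    for reps in replicates:
        for gamma in (0.01, 0.1, 0.5):
            specs.append(SimSpec(kind="BM", gamma=gamma, replicates=reps,
                                 n_genes=n_genes, label="neutral"))
            for alpha in (2.0, 10.0, 50.0):
                for gap in (0.5, 1.0, 2.0):
                    specs.append(SimSpec(
                        kind="OU2", alpha=alpha, gamma=gamma,
                        theta0=5.0, theta1=5.0 + gap,
                        replicates=reps, n_genes=n_genes, label="adaptive",
                    ))
    return specs


def _branch_theta(spec: SimSpec, regime: int) -> float:
    return spec.theta1 if (spec.kind == "OU2" and regime != BACKGROUND) else spec.theta0


def simulate_tips(
    tree: Phylogeny,
    painting: RegimePainting | None,
    spec: SimSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trait value per tip by exact transition sampling down the tree.

    Along a branch of length t the exact transition is
      BM:  child ~ N(parent, sigma^2 t)
      OU:  child ~ N(parent e^{-alpha t} + theta (1 - e^{-alpha t}),
                     sigma^2 (1 - e^{-2 alpha t}) / (2 alpha))
    with theta taken from the branch's regime.  The root starts at
    theta0 (the BM root state / background optimum).
    """
    if spec.kind == "OU2" and painting is None:
        raise ValueError("OU2 simulation requires a painting")
    ou = spec.kind != "BM" and spec.alpha > 0
    values = np.empty(tree.n_nodes)
    values[0] = spec.theta0
    for node in range(1, tree.n_nodes):
        parent_val = values[tree.parent[node]]
        t = tree.branch_length[node]
        regime = int(painting.branch_regime[node]) if painting is not None else BACKGROUND
        if ou:
            decay = np.exp(-spec.alpha * t)
            mean = parent_val * decay + _branch_theta(spec, regime) * (1.0 - decay)
            var = spec.sigma2 * (1.0 - decay**2) / (2.0 * spec.alpha)
        else:
            mean = parent_val
            var = spec.sigma2 * t
        values[node] = rng.normal(mean, np.sqrt(var)) if var > 0 else mean
    return values[tree.tip_ids]


def add_replicates(
    tip_values: np.ndarray,
    replicates: int | np.ndarray,
    gamma: float,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expand tip values into cells: value + N(0, gamma * sigma^2) per cell."""
    reps = np.full(len(tip_values), replicates) if np.isscalar(replicates) else np.asarray(replicates)
    if np.any(reps < 1):
        raise ValueError("every subline needs at least one replicate")
    expanded = np.repeat(np.asarray(tip_values, dtype=float), reps)
    sd = np.sqrt(gamma * sigma2)
    if sd > 0:
        expanded = expanded + rng.normal(0.0, sd, size=expanded.size)
    return expanded


@dataclass
class LabeledDataset:
    """Synthetic expression with per-gene ground truth."""

    dataset: ExpressionDataset
    truth: pd.DataFrame = field(repr=False)  # gene, label, kind, alpha, gamma, theta0, theta1, replicates

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.truth.loc[self.truth["label"] == label, "gene"])

    def write(self, expression_path, mapping_path, truth_path) -> None:
        self.dataset.write(expression_path, mapping_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)


def _gene_rng(seed: int, condition_index: int, gene_index: int) -> np.random.Generator:
    # stable per-gene stream: subsets of the grid reproduce exactly
    return np.random.default_rng([seed, condition_index, gene_index])


def make_grid_dataset(
    tree: Phylogeny,
    painting: RegimePainting,
    grid: list[SimSpec],
    seed: int,
    scale: str = "gaussian",
) -> LabeledDataset:
    """Concatenate simulated genes across grid conditions with truth labels.

    All conditions share one replicate count (cells are columns of a
    single matrix); ``scale`` is "gaussian" (trait scale) or "tpm-like"
    (2^x - 1 clipped at 0, the inverse of the log2(x + 1) analysis
    transform).
    """
    if not grid:
        raise ValueError("empty simulation grid")
    reps = {s.replicates for s in grid}
    if len(reps) > 1:
        raise ValueError("one grid dataset must use a single replicate count; "
                         "build one dataset per replicate level")
    if scale not in ("gaussian", "tpm-like"):
        raise ValueError(f"unknown scale {scale!r}")
    r = reps.pop()
    cells = [f"{name}_cell{j}" for name in tree.tip_names for j in range(1, r + 1)]
    cell_to_subline = {c: c.rsplit("_cell", 1)[0] for c in cells}

    rows, truth_rows, genes = [], [], []
    for ci, spec in enumerate(grid):
        for gi in range(spec.n_genes):
            rng = _gene_rng(seed, ci, gi)
            tips = simulate_tips(tree, painting if spec.kind == "OU2" else None, spec, rng)
            row = add_replicates(tips, r, spec.gamma, spec.sigma2, rng)
            gene = f"g{ci:03d}_{spec.label}_{gi:04d}"
            if gene in genes:
                raise ValueError(f"duplicate gene id {gene}")
            genes.append(gene)
            rows.append(row)
            truth_rows.append({
                "gene": gene, "label": spec.label, "kind": spec.kind,
                "alpha": spec.alpha, "sigma2": spec.sigma2, "gamma": spec.gamma,
                "theta0": spec.theta0, "theta1": spec.theta1, "replicates": r,
                "condition": ci,
            })
    values = np.vstack(rows)
    if scale == "tpm-like":
        values = to_tpm_like(values)
    dataset = ExpressionDataset(
        genes=genes, cells=cells, values=values, cell_to_subline=cell_to_subline
    )
    return LabeledDataset(dataset=dataset, truth=pd.DataFrame(truth_rows))


def to_tpm_like(values: np.ndarray) -> np.ndarray:
    """Monotone map onto a nonnegative TPM-like scale: max(2^x - 1, 0)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    return np.clip(np.exp2(values) - 1.0, 0.0, None)
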