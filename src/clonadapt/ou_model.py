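"""Gaussian likelihood machinery for BM / OU models with replicate cells.

Expression of one gene evolves along the subline phylogeny as either
Brownian motion (neutral drift), a one-optimum Ornstein-Uhlenbeck
process (constrained), or a two-optima OU process whose optimum switches
with the branch regime (adaptive).  Each subline contributes several
single cells, modelled as the subline's trait value plus i.i.d. Gaussian
noise of variance gamma * sigma^2.

All three models are linear-Gaussian in the mean parameters, so a gene's
cell-value vector y satisfies

    y ~ N(W theta, sigma^2 * C0(alpha, gamma)),

with W the Hansen design matrix (a single all-ones column for BM/OU1)
and C0 the unit-sigma^2 covariance.  theta and sigma^2 are profiled out
in closed form (GLS / maximum likelihood); only (alpha, gamma) need
numerical optimization.

The root state is fixed: for BM it is the free mean x0; for OU models it
is tied to the background optimum theta_0 (ouch-style Hansen models).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg as sla

from .dataset import ExpressionDataset
from .phylo import BACKGROUND, Phylogeny, RegimePainting, regime_segments

MODEL_KINDS = ("BM", "OU1", "OU2")

# free parameters per model: BM {x0, sigma2, gamma}; OU1 {theta, alpha,
# sigma2, gamma}; OU2 adds the chosen-regime optimum
N_PARAMS = {"BM": 3, "OU1": 4, "OU2": 5}


class DegenerateGeneError(ValueError):
    """Gene/system combination with no proper Gaussian likelihood."""


@dataclass(frozen=True)
class ModelParams:
    kind: str
    alpha: float        # selection strength; 0 for BM
    sigma2: float       # diffusion variance
    gamma: float        # replicate-noise ratio: cell noise variance = gamma*sigma2
    theta: tuple[float, ...]  # () for BM; (theta,) OU1; (theta0, theta1) OU2
    x0: float           # root state; for OU kinds equals theta[0]

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be nonnegative")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite optimum")


def bm_tip_cov(tree: Phylogeny) -> np.ndarray:
    """Brownian tip covariance at unit sigma^2: Cov(X_i, X_j) = depth(MRCA)."""
    return tree.mrca_depths()


def ou_tip_cov(tree: Phylogeny, alpha: float) -> np.ndarray:
    """OU tip covariance at unit sigma^2 with the root state held fixed.

    For tips i, j at depths T_i, T_j with MRCA depth t_a,

        Cov = exp(-alpha (T_i + T_j - 2 t_a)) * (1 - exp(-2 alpha t_a)) / (2 alpha),

    which tends to the BM covariance t_a as alpha -> 0 (that limit is
    returned exactly at alpha == 0).
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    ta = tree.mrca_depths()
    if alpha == 0:
        return ta
    T = tree.tip_depths()
    tsum = T[:, None] + T[None, :]
    return np.exp(-alpha * (tsum - 2.0 * ta)) * (1.0 - np.exp(-2.0 * alpha * ta)) / (2.0 * alpha)


@lru_cache(maxsize=64)
def _segment_arrays(tree: Phylogeny, painting: RegimePainting):
    """Flattened (tip_row, start, end, regime) arrays over all tips' segments."""
    rows, starts, ends, regimes = [], [], [], []
    for i, name in enumerate(tree.tip_names):
        for s, e, r in regime_segments(tree, painting, name).segments:
            rows.append(i)
            starts.append(s)
            ends.append(e)
            regimes.append(r)
    return (np.array(rows), np.array(starts), np.array(ends), np.array(regimes))


def ou_weight_matrix(tree: Phylogeny, painting: RegimePainting, alpha: float) -> np.ndarray:
    """Hansen mean weights: (n_tips, 2) matrix with rows summing to 1.

    The expected tip value is x0 e^{-alpha T} plus, for each regime
    segment [s, e] of the root-to-tip path, theta_regime *
    (e^{-alpha(T-e)} - e^{-alpha(T-s)}).  With x0 tied to the background
    optimum, the residual weight e^{-alpha T} goes to column 0.
    """
    if alpha <= 0:
        raise ValueError("ou_weight_matrix requires alpha > 0; BM uses a single ones column")
    rows, starts, ends, regimes = _segment_arrays(tree, painting)
    T = tree.tip_depths()
    W = np.zeros((tree.n_tips, 2))
    W[:, BACKGROUND] = np.exp(-alpha * T)
    contrib = np.exp(-alpha * (T[rows] - ends)) - np.exp(-alpha * (T[rows] - starts))
    np.add.at(W, (rows, regimes), contrib)
    return W


@dataclass
class GaussianSystem:
    """Cell-level mean design W and scaled covariance C0 for one model.

    Full covariance is sigma^2 * C0 with C0 = Z V0 Z^T + gamma I, where Z
    expands tips to cells and V0 is the unit-sigma^2 tip covariance.
    """

    W: np.ndarray        # (n_cells, n_mean_params)
    C0: np.ndarray       # (n_cells, n_cells)
    kind: str

    @property
    def n_cells(self) -> int:
        return self.C0.shape[0]


def cell_indicator(tree: Phylogeny, dataset: ExpressionDataset) -> np.ndarray:
    """Z: (n_cells, n_tips) 0/1 matrix mapping each cell to its subline."""
    cached = getattr(dataset, "_indicator_cache", None)
    if cached is not None and cached[0] is tree:
        return cached[1]
    Z = np.zeros((dataset.n_cells, tree.n_tips))
    for j, cell in enumerate(dataset.cells):
        Z[j, tree.tip_index(dataset.cell_to_subline[cell])] = 1.0
    dataset._indicator_cache = (tree, Z)
    return Z


def assemble_system(
    tree: Phylogeny,
    painting: RegimePainting | None,
    kind: str,
    alpha: float,
    gamma: float,
    dataset: ExpressionDataset,
    gene: str | None = None,
) -> GaussianSystem:
    """Build the cell-level Gaussian system for one model at (alpha, gamma).

    ``gene`` is only validated for presence; the system itself depends on
    the tree, the painting, the cell->subline structure and (alpha, gamma).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if gene is not None:
        dataset.gene_index(gene)
    Z = cell_indicator(tree, dataset)

    if kind == "BM":
        V0 = bm_tip_cov(tree)
        Wtip = np.ones((tree.n_tips, 1))
    elif kind == "OU1":
        V0 = ou_tip_cov(tree, alpha)
        Wtip = np.ones((tree.n_tips, 1))  # x0 = theta: constant mean
    else:
        if painting is None:
            raise ValueError("OU2 requires a regime painting")
        V0 = ou_tip_cov(tree, alpha)
        Wtip = (
            ou_weight_matrix(tree, painting, alpha)
            if alpha > 0
            else np.ones((tree.n_tips, 1))
        )

    C0 = Z @ V0 @ Z.T + gamma * np.eye(dataset.n_cells)
    if gamma == 0:
        counts = Z.sum(axis=0)
        if np.any(counts > 1):
            raise DegenerateGeneError(
                "gamma = 0 with replicated sublines makes the cell covariance singular"
            )
    return GaussianSystem(W=Z @ Wtip, C0=C0, kind=kind)


def profile_loglik(system: GaussianSystem, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profile the mean and variance out of the Gaussian log-likelihood.

    Returns ``(loglik, theta_hat, sigma2_hat)`` where theta_hat is the GLS
    estimate (W^T C0^-1 W)^-1 W^T C0^-1 y (computed by whitened least
    squares for stability), sigma2_hat the ML variance RSS/n, and loglik
    the exact multivariate-normal log-density at the profiled optimum:

        -(n/2) log(2 pi sigma2_hat) - (1/2) log|C0| - n/2.
    """
    y = np.asarray(y, dtype=float)
    n = system.n_cells
    k = system.W.shape[1]
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    if n < k + 1:
        raise DegenerateGeneError(f"n = {n} cells cannot identify {k} mean params + variance")
    if np.ptp(y) == 0:
        raise DegenerateGeneError("constant expression across all cells")

    try:
        L = sla.cholesky(system.C0, lower=True)
    except sla.LinAlgError as exc:
        raise DegenerateGeneError(f"covariance not positive definite: {exc}") from exc
    A = sla.solve_triangular(L, system.W, lower=True)
    b = sla.solve_triangular(L, y, lower=True)
    theta_hat, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ theta_hat
    sigma2_hat = float(resid @ resid) / n
    if sigma2_hat <= 0 or not np.isfinite(sigma2_hat):
        raise DegenerateGeneError("zero residual variance: y lies in the mean column space")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2_hat) - 0.5 * logdet - 0.5 * n
    return float(loglik), np.atleast_1d(theta_hat), sigma2_hat
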