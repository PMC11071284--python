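"""Per-gene model fitting, likelihood-ratio tests, and adaptation calls.

For every gene and regime the scan fits the neutral (BM), constrained
(OU1) and adaptive (OU2) models by maximum likelihood, tests each OU
model against BM with a likelihood-ratio test, corrects p-values across
genes with Benjamini-Hochberg, and labels genes adaptive (up or down by
the sign of theta1_hat - theta0_hat) at corrected p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as sopt
import scipy.stats as sstats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset
from .ou_model import (
    MODEL_KINDS,
    N_PARAMS,
    DegenerateGeneError,
    GaussianSystem,
    assemble_system,
    profile_loglik,
)
from .phylo import Phylogeny, RegimePainting

logger = logging.getLogger(__name__)

# bounded search over (log alpha, log gamma)
ALPHA_BOUNDS = (1e-4, 1e3)
GAMMA_BOUNDS = (1e-6, 1e2)
DEFAULT_INIT = (0.1, 0.01)  # (alpha0, gamma0)
# multi-start: the default init plus two fixed multiplicative jitters
START_FACTORS = ((1.0, 1.0), (20.0, 20.0), (0.05, 0.05))

CALL_LEVELS = ("adaptive-up", "adaptive-down", "constrained", "neutral")


@dataclass
class ModelFit:
    kind: str
    alpha: float
    gamma: float
    sigma2: float
    theta: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    message: str = ""
    n_starts: int = 1

    @property
    def x0(self) -> float:
        return float(self.theta[0])


def fit_model(
    dataset: ExpressionDataset,
    gene: str,
    tree: Phylogeny,
    painting: RegimePainting | None,
    kind: str,
    init: tuple[float, float] = DEFAULT_INIT,
) -> ModelFit:
    """Maximum-likelihood fit of one model to one gene.

    (alpha, gamma) are optimized by bounded L-BFGS-B on the log scale
    with multiple starts; theta and sigma^2 come from GLS profiling.  BM
    has no alpha, so only gamma is searched.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    y = dataset.gene_values(gene)
    if np.ptp(y) == 0:
        raise DegenerateGeneError(f"gene {gene!r} is constant across cells")

    def system_at(alpha: float, gamma: float) -> GaussianSystem:
        return assemble_system(tree, painting, kind, alpha, gamma, dataset)

    la_lo, la_hi = np.log(ALPHA_BOUNDS)
    lg_lo, lg_hi = np.log(GAMMA_BOUNDS)

    def negll(z: np.ndarray) -> float:
        alpha = float(np.exp(z[0])) if kind != "BM" else 0.0
        gamma = float(np.exp(z[-1]))
        try:
            ll, _, _ = profile_loglik(system_at(alpha, gamma), y)
        except DegenerateGeneError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    best = None
    any_converged = False
    for fa, fg in START_FACTORS:
        a0 = float(np.clip(init[0] * fa, *ALPHA_BOUNDS))
        g0 = float(np.clip(init[1] * fg, *GAMMA_BOUNDS))
        if kind == "BM":
            z0 = np.array([np.log(g0)])
            bounds = [(lg_lo, lg_hi)]
        else:
            z0 = np.log([a0, g0])
            bounds = [(la_lo, la_hi), (lg_lo, lg_hi)]
        res = sopt.minimize(negll, z0, method="L-BFGS-B", bounds=bounds)
        any_converged |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    alpha_hat = float(np.exp(best.x[0])) if kind != "BM" else 0.0
    gamma_hat = float(np.exp(best.x[-1]))
    ll, theta_hat, sigma2_hat = profile_loglik(system_at(alpha_hat, gamma_hat), y)
    return ModelFit(
        kind=kind,
        alpha=alpha_hat,
        gamma=gamma_hat,
        sigma2=sigma2_hat,
        theta=theta_hat,
        loglik=ll,
        n_params=N_PARAMS[kind],
        converged=any_converged and np.isfinite(ll),
        message=str(best.message),
        n_starts=len(START_FACTORS),
    )


def lrt(alt: ModelFit, null: ModelFit) -> float:
    """Likelihood-ratio p-value of a nested pair (BM within OU1 within OU2).

    The statistic max(0, 2 * (ll_alt - ll_null)) is referred to a
    chi-square with df = difference in free-parameter counts; small
    negative statistics from optimizer noise are clamped to zero.
    """
    order = {k: i for i, k in enumerate(MODEL_KINDS)}
    if order[alt.kind] <= order[null.kind]:
        raise ValueError(f"{null.kind} is not nested in {alt.kind}")
    df = alt.n_params - null.n_params
    stat = max(0.0, 2.0 * (alt.loglik - null.loglik))
    return float(sstats.chi2.sf(stat, df)) if stat > 0 else 1.0


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    q_adaptive: float,
    q_constrained: float,
    theta0_hat: float,
    theta1_hat: float,
    q_threshold: float = 0.05,
) -> tuple[str, str]:
    """Label one gene and give the direction of adaptation.

    Adaptive if the OU2-vs-BM corrected p is below threshold, with
    direction up/down by comparing the chosen optimum to the background
    optimum; otherwise constrained if the OU1-vs-BM corrected p is below
    threshold; otherwise neutral.
    """
    if q_adaptive < q_threshold:
        if theta1_hat > theta0_hat:
            return "adaptive-up", "up"
        if theta1_hat < theta0_hat:
            return "adaptive-down", "down"
        logger.warning("adaptive call with exactly tied optima")
        return "adaptive-up", "tied"
    if q_constrained < q_threshold:
        return "constrained", ""
    return "neutral", ""


@dataclass
class GeneScanResult:
    """Per-regime scan output plus bookkeeping of skipped genes."""

    regime: str
    table: pd.DataFrame = field(repr=False)
    skipped: list[str] = field(default_factory=list)

    def calls(self) -> pd.Series:
        return self.table["call"]

    def adaptive_genes(self) -> list[str]:
        return list(self.table.loc[self.table["call"].str.startswith("adaptive"), "gene"])


SCAN_COLUMNS = [
    "gene", "loglik_bm", "loglik_ou1", "loglik_ou2",
    "alpha", "gamma", "sigma2", "theta0", "theta1",
    "p_adaptive", "q_adaptive", "p_constrained", "q_constrained",
    "call", "direction",
]


def scan_regime(
    dataset: ExpressionDataset,
    tree: Phylogeny,
    painting: RegimePainting,
    regime_name: str = "chosen",
    q_threshold: float = 0.05,
    init: tuple[float, float] = DEFAULT_INIT,
) -> GeneScanResult:
    """Fit all three models to every gene and call adaptation for one regime.

    BH correction is applied across the genes of this scan, separately
    for the adaptive and constrained tests; regimes are independent runs.
    """
    rows = []
    skipped: list[str] = []
    for gene in dataset.genes:
        try:
            fit_bm = fit_model(dataset, gene, tree, None, "BM", init)
            fit_ou1 = fit_model(dataset, gene, tree, None, "OU1", init)
            fit_ou2 = fit_model(dataset, gene, tree, painting, "OU2", init)
        except DegenerateGeneError as exc:
            logger.info("skipping gene %s: %s", gene, exc)
            skipped.append(gene)
            continue
        if not (fit_bm.converged and fit_ou1.converged and fit_ou2.converged):
            logger.info("skipping gene %s: optimizer did not converge", gene)
            skipped.append(gene)
            continue
        rows.append({
            "gene": gene,
            "loglik_bm": fit_bm.loglik,
            "loglik_ou1": fit_ou1.loglik,
            "loglik_ou2": fit_ou2.loglik,
            "alpha": fit_ou2.alpha,
            "gamma": fit_ou2.gamma,
            "sigma2": fit_ou2.sigma2,
            "theta0": float(fit_ou2.theta[0]),
            "theta1": float(fit_ou2.theta[1]) if fit_ou2.theta.size > 1 else float(fit_ou2.theta[0]),
            "p_adaptive": lrt(fit_ou2, fit_bm),
            "p_constrained": lrt(fit_ou1, fit_bm),
        })
    if not rows:
        table = pd.DataFrame(columns=SCAN_COLUMNS)
        return GeneScanResult(regime=regime_name, table=table, skipped=skipped)

    table = pd.DataFrame(rows)
    table["q_adaptive"] = bh_fdr(table["p_adaptive"].to_numpy())
    table["q_constrained"] = bh_fdr(table["p_constrained"].to_numpy())
    calls = [
        classify(qa, qc, t0, t1, q_threshold)
        for qa, qc, t0, t1 in zip(
            table["q_adaptive"], table["q_constrained"], table["theta0"], table["theta1"]
        )
    ]
    table["call"] = [c for c, _ in calls]
    table["direction"] = [d for _, d in calls]
    table = table[SCAN_COLUMNS]
    n_up = int((table["call"] == "adaptive-up").sum())
    n_down = int((table["call"] == "adaptive-down").sum())
    logger.info(
        "regime %s: %d genes scanned, %d adaptive-up, %d adaptive-down, %d skipped",
        regime_name, len(table), n_up, n_down, len(skipped),
    )
    return GeneScanResult(regime=regime_name, table=table, skipped=skipped)
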