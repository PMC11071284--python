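"""Post-scan analyses: clustering, DE comparator, enrichment, scores.

These operations consume scan tables (gene calls and corrected
p-values), a DEG table from an external differential-expression run,
and GMT gene-set files; none of them touch the likelihood machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sstats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dataset import ExpressionDataset
from .inference import GeneScanResult, bh_fdr

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


def cluster_values(
    scans: dict[str, GeneScanResult],
    use_q: bool = True,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Signed log2 p triplets for genes adaptive in at least one regime.

    For each regime r the value is log2 p if adaptively up-regulated,
    -log2 p if adaptively down-regulated, 0 otherwise (so up-regulation
    is negative, since p < 1; ``flip_sign`` negates for display).  By
    default the BH-corrected p (q) feeds the formula; ``use_q=False``
    uses the raw LRT p.
    """
    frames = {}
    universe: list[str] | None = None
    for regime, scan in scans.items():
        t = scan.table.set_index("gene")
        if universe is None:
            universe = list(t.index)
        elif set(universe) != set(t.index):
            raise ValueError("scans cover different gene universes")
        p = t["q_adaptive"] if use_q else t["p_adaptive"]
        p = p.clip(lower=_TINY)
        v = pd.Series(0.0, index=t.index)
        up = t["call"] == "adaptive-up"
        down = t["call"] == "adaptive-down"
        v[up] = np.log2(p[up])
        v[down] = -np.log2(p[down])
        if (p[up | down] <= _TINY).any():
            logger.warning("regime %s: p-values clamped to %.3g", regime, _TINY)
        frames[regime] = v
    out = pd.DataFrame(frames)
    out = out.loc[(out != 0).any(axis=1)]
    if flip_sign:
        out = -out
    return out


@dataclass
class ClusteringResult:
    assignments: pd.Series
    chosen_k: int
    silhouette_by_k: dict[int, float]
    criterion: str


def kmeans_clusters(
    values: pd.DataFrame,
    k_range: range = range(2, 21),
    seed: int = 0,
    criterion: str = "max",
    n_init: int = 10,
) -> ClusteringResult:
    """k-means over the signed log-p triplets with silhouette-based k.

    ``criterion`` picks k with the best ("max", conventional) or worst
    ("min") mean silhouette; both are offered because published
    protocols differ in wording.  Euclidean distance on the raw
    (unscaled) triplets; fixed seed makes the partition reproducible.
    """
    if criterion not in ("max", "min"):
        raise ValueError("criterion must be 'max' or 'min'")
    X = values.to_numpy(dtype=float)
    n = len(X)
    if n < 2 or np.ptp(X) == 0:
        raise ValueError("degenerate input: need >= 2 distinct points to cluster")
    ks = [k for k in k_range if k < n]
    if not ks:
        raise ValueError("no feasible k below the number of genes")
    if max(k_range) >= n:
        logger.warning("k range capped at %d (only %d genes)", max(ks), n)

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(X, lab))
        labels_by_k[k] = lab
    if not sil:
        raise ValueError("no k produced a valid partition")
    pick = max if criterion == "max" else min
    chosen_k = pick(sil, key=lambda k: (sil[k], -k))
    return ClusteringResult(
        assignments=pd.Series(labels_by_k[chosen_k], index=values.index, name="cluster"),
        chosen_k=chosen_k,
        silhouette_by_k=sil,
        criterion=criterion,
    )


def de_ttest(
    dataset: ExpressionDataset,
    chosen_tips: set[str],
    background_tips: set[str] | None = None,
) -> pd.Series:
    """Two-sided Welch t-test per gene, chosen-subline cells vs background cells.

    The naive differential-expression comparator of the simulation
    study: it ignores the phylogenetic correlation between cells, which
    is exactly why it over-calls on neutral data.
    """
    sublines = np.array([dataset.cell_to_subline[c] for c in dataset.cells])
    if background_tips is None:
        background_tips = set(sublines) - set(chosen_tips)
    in_chosen = np.isin(sublines, sorted(chosen_tips))
    in_bg = np.isin(sublines, sorted(background_tips))
    if in_chosen.sum() < 2 or in_bg.sum() < 2:
        raise ValueError("need at least 2 cells on each side of the t-test")
    res = sstats.ttest_ind(
        dataset.values[:, in_chosen], dataset.values[:, in_bg],
        axis=1, equal_var=False,
    )
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=dataset.genes, name="p_de")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora(
    hit_genes: set[str],
    gene_sets: dict[str, set[str]],
    background_genes: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each gene set.

    All sets are intersected with the background universe first; the
    upper-tail probability of drawing at least the observed overlap is
    BH-corrected across sets.
    """
    hits = set(hit_genes) & set(background_genes)
    if set(hit_genes) - set(background_genes):
        raise ValueError("hit genes outside the background universe")
    M = len(background_genes)
    N = len(hits)
    rows = []
    for name, genes in gene_sets.items():
        in_bg = genes & set(background_genes)
        if not in_bg:
            logger.warning("gene set %s has no background overlap; dropped", name)
            continue
        K = len(in_bg)
        k = len(in_bg & hits)
        p = float(sstats.hypergeom.sf(k - 1, M, K, N))
        rows.append({"gene_set": name, "hits_in_set": k, "set_size": K,
                     "background_size": M, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["gene_set", "hits_in_set", "set_size",
                                        "background_size", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    return table


def signature_score(dataset: ExpressionDataset, gene_list: list[str]) -> pd.Series:
    """Per-cell mean expression over a gene list (e.g. CD8 = mean of Cd8a, Cd8b)."""
    present = [g for g in gene_list if g in dataset.genes]
    missing = [g for g in gene_list if g not in dataset.genes]
    if not present:
        raise ValueError("no signature gene present in the dataset")
    if missing:
        logger.warning("signature genes missing from dataset: %s", missing)
    idx = [dataset.gene_index(g) for g in present]
    return pd.Series(dataset.values[idx].mean(axis=0), index=dataset.cells, name="score")


def deg_adaptive_enrichment(
    deg_table: pd.DataFrame,
    scan: GeneScanResult,
    regime: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Share of adaptive genes within each DEG direction class + 2x2 chi-square.

    ``deg_table`` needs columns ``gene`` and ``direction`` (two classes,
    e.g. up in responders vs up in non-responders), already restricted
    to significant DEGs.  Genes absent from the scan universe are
    dropped.  Returns a per-class table of percent adaptive-up /
    adaptive-down and the chi-square p of the 2x2 adaptive-up vs
    adaptive-down by DEG-class contingency (no continuity correction).
    """
    calls = scan.table.set_index("gene")["call"]
    deg = deg_table.loc[deg_table["gene"].isin(calls.index)].copy()
    classes = list(pd.unique(deg["direction"]))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 DEG direction classes, got {classes}")
    rows = []
    counts = np.zeros((2, 2), dtype=int)
    for i, cls in enumerate(classes):
        genes = deg.loc[deg["direction"] == cls, "gene"]
        if len(genes) == 0:
            raise ValueError(f"empty DEG class {cls!r}")
        sub = calls.loc[genes]
        n_up = int((sub == "adaptive-up").sum())
        n_down = int((sub == "adaptive-down").sum())
        counts[i] = (n_up, n_down)
        rows.append({
            "deg_class": cls, "n_degs": len(genes),
            "n_adaptive_up": n_up, "n_adaptive_down": n_down,
            "pct_adaptive_up": 100.0 * n_up / len(genes),
            "pct_adaptive_down": 100.0 * n_down / len(genes),
        })
    table = pd.DataFrame(rows)
    if counts.sum() == 0 or (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        logger.warning("degenerate adaptive contingency table; chi-squared skipped")
        return table, float("nan")
    chi2 = sstats.chi2_contingency(counts, correction=False)
    return table, float(chi2.pvalue)
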