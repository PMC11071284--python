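"""End-to-end orchestration: config, regime scans, and the simulation study.

Two entry points matter to most users:

* :func:`run_scan` — scan a real (or simulated) expression matrix for
  adaptive genes, one independent run per regime, writing one TSV per
  regime.
* :func:`run_simulation_study` — the validation loop: simulate labeled
  data on the fixture (or a user) tree, run the scan and the naive
  t-test comparator, and report power / false-positive rates per
  condition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import ExpressionDataset, filter_genes, read_expression
from .downstream import de_ttest
from .inference import DEFAULT_INIT, GeneScanResult, bh_fdr, scan_regime
from .phylo import Phylogeny, normalize_height, paint_regime, parse_tree
from .synthetic import LabeledDataset, SimSpec, fixture_tree, FIXTURE_REGIMES, make_grid_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    tree_path: str
    expression_path: str
    mapping_path: str
    regimes: dict[str, list[str]]
    q_threshold: float = 0.05
    transform: str = "log2p1"
    min_expressed_fraction: float = 0.5
    init_alpha: float = DEFAULT_INIT[0]
    init_gamma: float = DEFAULT_INIT[1]
    seed: int = 0
    output_dir: str = "results"
    max_gene_failure_fraction: float = 0.2

    def validate(self) -> None:
        for p in (self.tree_path, self.expression_path, self.mapping_path):
            if not Path(p).exists():
                raise ConfigError(f"missing input file: {p}")
        if not self.regimes:
            raise ConfigError("no regimes configured")
        if not 0 < self.q_threshold < 1:
            raise ConfigError("q_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_regimes(path: str | Path) -> dict[str, list[str]]:
    """Regime config file: YAML mapping of regime name -> tip-name list."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"regime file {path} must map regime names to tip lists")
    return {str(k): [str(t) for t in v] for k, v in raw.items()}


def prepare_inputs(config: RunConfig) -> tuple[Phylogeny, ExpressionDataset]:
    """Read and validate the tree and expression inputs; filter and transform."""
    config.validate()
    tree = normalize_height(parse_tree(Path(config.tree_path).read_text()))
    dataset = read_expression(config.expression_path, config.mapping_path, tree=tree)
    for regime, tips in config.regimes.items():
        unknown = set(tips) - set(tree.tip_names)
        if unknown:
            raise ConfigError(f"regime {regime} references unknown tips: {sorted(unknown)}")
    dataset, dropped = filter_genes(dataset, config.min_expressed_fraction)
    if dropped:
        logger.info("filtered out %d genes", len(dropped))
    if dataset.n_genes == 0:
        raise ConfigError("no genes left after filtering")
    return tree, dataset.transformed(config.transform)


def run_scan(config: RunConfig) -> dict[str, GeneScanResult]:
    """Scan every configured regime independently and write one TSV each."""
    tree, dataset = prepare_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, GeneScanResult] = {}
    for regime, tips in config.regimes.items():
        painting = paint_regime(tree, set(tips))
        scan = scan_regime(
            dataset, tree, painting, regime_name=regime,
            q_threshold=config.q_threshold,
            init=(config.init_alpha, config.init_gamma),
        )
        frac_failed = len(scan.skipped) / max(1, len(scan.skipped) + len(scan.table))
        if frac_failed > config.max_gene_failure_fraction:
            raise RuntimeError(
                f"regime {regime}: {frac_failed:.1%} of genes failed numerically"
            )
        scan.table.to_csv(outdir / f"scan_{regime}.tsv", sep="\t", index=False)
        results[regime] = scan
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_genes": dataset.n_genes,
        "regimes": list(config.regimes),
    }
    (outdir / "scan_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return results


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

NEUTRAL_GAMMAS = (0.01, 0.1, 0.5)
STRONGEST_ADAPTIVE = SimSpec(
    kind="OU2", alpha=50.0, gamma=0.01, theta0=5.0, theta1=7.0,
    replicates=8, n_genes=200, label="adaptive",
)


def neutral_grid(n_per_condition: int = 170,
                 replicates: tuple[int, ...] = (4, 8)) -> list[SimSpec]:
    """Neutral BM conditions spanning the replicate-noise grid."""
    return [
        SimSpec(kind="BM", gamma=g, replicates=r, n_genes=n_per_condition, label="neutral")
        for r in replicates for g in NEUTRAL_GAMMAS
    ]


@dataclass
class StudyMetrics:
    """Power / false-positive summary of one simulation study run."""

    per_condition: pd.DataFrame = field(repr=False)
    scan_fpr_pct: float          # % of truth-neutral genes called adaptive
    scan_power_pct: float        # % of truth-adaptive genes called adaptive
    de_fpr_pct: float            # same, naive t-test comparator
    de_power_pct: float
    n_neutral: int
    n_adaptive: int
    seed: int


def _simulate_by_replicate_level(
    grid: list[SimSpec], tree: Phylogeny, painting, seed: int, scale: str
) -> list[LabeledDataset]:
    datasets = []
    for r in sorted({s.replicates for s in grid}):
        sub = [s for s in grid if s.replicates == r]
        # keep global condition indices so per-gene seeds are subset-stable
        idx = [grid.index(s) for s in sub]
        lab = make_grid_dataset(tree, painting, sub, seed=seed, scale=scale)
        lab.truth["condition"] = [idx[c] for c in lab.truth["condition"]]
        datasets.append(lab)
    return datasets


def run_simulation_study(
    grid: list[SimSpec],
    seed: int,
    tree: Phylogeny | None = None,
    chosen_tips: tuple[str, ...] = FIXTURE_REGIMES["HA-R"],
    q_threshold: float = 0.05,
    scale: str = "tpm-like",
    transform: str = "log2p1",
) -> StudyMetrics:
    """Simulate a labeled grid, scan it, and benchmark against the t-test.

    One dataset (and hence one BH family for each of the scan and the
    comparator) per replicate level; metrics are pooled over datasets
    and also reported per condition.  Deterministic given ``seed``.
    """
    if not grid:
        raise ValueError("empty simulation grid")
    if tree is None:
        tree = fixture_tree()
    painting = paint_regime(tree, set(chosen_tips))

    frames = []
    for lab in _simulate_by_replicate_level(grid, tree, painting, seed, scale):
        ds = lab.dataset.transformed(transform) if scale == "tpm-like" else lab.dataset
        scan = scan_regime(ds, tree, painting, regime_name="study", q_threshold=q_threshold)
        p_de = de_ttest(ds, set(chosen_tips))
        q_de = pd.Series(bh_fdr(p_de.to_numpy()), index=p_de.index)
        t = lab.truth.merge(scan.table[["gene", "call", "q_adaptive"]], on="gene", how="inner")
        t["adaptive_call"] = t["call"].str.startswith("adaptive")
        t["de_call"] = (q_de.loc[t["gene"]] < q_threshold).to_numpy()
        frames.append(t)
    pooled = pd.concat(frames, ignore_index=True)

    per_cond = (
        pooled.groupby(["condition", "label", "kind", "alpha", "gamma",
                        "theta0", "theta1", "replicates"], as_index=False)
        .agg(n=("gene", "size"),
             scan_called_pct=("adaptive_call", lambda s: 100.0 * s.mean()),
             de_called_pct=("de_call", lambda s: 100.0 * s.mean()))
    )
    neutral = pooled[pooled["label"] == "neutral"]
    adaptive = pooled[pooled["label"] == "adaptive"]

    def pct(mask: pd.Series) -> float:
        return float(100.0 * mask.mean()) if len(mask) else float("nan")

    metrics = StudyMetrics(
        per_condition=per_cond,
        scan_fpr_pct=pct(neutral["adaptive_call"]),
        scan_power_pct=pct(adaptive["adaptive_call"]),
        de_fpr_pct=pct(neutral["de_call"]),
        de_power_pct=pct(adaptive["de_call"]),
        n_neutral=len(neutral),
        n_adaptive=len(adaptive),
        seed=seed,
    )
    logger.info(
        "study: scan FPR %.2f%% (n=%d), scan power %.2f%% (n=%d), "
        "DE FPR %.2f%%, DE power %.2f%%",
        metrics.scan_fpr_pct, metrics.n_neutral,
        metrics.scan_power_pct, metrics.n_adaptive,
        metrics.de_fpr_pct, metrics.de_power_pct,
    )
    return metrics
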