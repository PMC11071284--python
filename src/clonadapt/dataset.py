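"""Expression data containers and TSV readers.

The pipeline consumes a gene x cell expression matrix (TPM-like,
nonnegative) plus a two-column table mapping each cell to the subline
(tree tip) it was sequenced from.  Individual cells of a subline act as
biological replicates of that subline's expression state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .phylo import Phylogeny


class DataError(ValueError):
    """Raised for malformed or inconsistent expression input."""


def log2p1(x: np.ndarray) -> np.ndarray:
    """Default analysis transform: log2(x + 1), tames TPM heavy tails."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log2p1": log2p1,
    "identity": lambda x: np.asarray(x, dtype=float),
}


@dataclass
class ExpressionDataset:
    """Gene x cell matrix with a cell -> subline map.

    ``values`` rows align with ``genes``, columns with ``cells``;
    ``cell_to_subline`` maps every cell id to a tip name.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray                # (n_genes, n_cells)
    cell_to_subline: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        missing = [c for c in self.cells if c not in self.cell_to_subline]
        if missing:
            raise DataError(f"cells with no subline mapping: {missing[:5]}")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise DataError(f"unknown gene: {gene!r}") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def sublines(self) -> list[str]:
        """Subline names in first-appearance cell order."""
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(self.cell_to_subline[c], None)
        return list(seen)

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cells:
            s = self.cell_to_subline[c]
            counts[s] = counts.get(s, 0) + 1
        return counts

    def validate_against_tree(self, tree: Phylogeny) -> None:
        tips = set(tree.tip_names)
        bad = sorted({s for s in self.cell_to_subline.values() if s not in tips})
        if bad:
            raise DataError(f"sublines not present as tree tips: {bad}")

    def transformed(self, transform: str = "log2p1") -> "ExpressionDataset":
        """Return a copy with the named transform applied to the matrix."""
        if transform not in TRANSFORMS:
            raise DataError(f"unknown transform {transform!r}; options: {sorted(TRANSFORMS)}")
        return ExpressionDataset(
            genes=list(self.genes),
            cells=list(self.cells),
            values=TRANSFORMS[transform](self.values),
            cell_to_subline=dict(self.cell_to_subline),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def write(self, expression_path: str | Path, mapping_path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(expression_path, sep="\t")
        pd.DataFrame(
            {"cell": self.cells,
             "subline": [self.cell_to_subline[c] for c in self.cells]}
        ).to_csv(mapping_path, sep="\t", index=False)


def read_expression(
    expression_path: str | Path,
    mapping_path: str | Path,
    tree: Phylogeny | None = None,
) -> ExpressionDataset:
    """Read the expression TSV (first column gene id) and the cell map TSV."""
    df = pd.read_csv(expression_path, sep="\t", index_col=0)
    mapping = pd.read_csv(mapping_path, sep="\t")
    if mapping.shape[1] < 2:
        raise DataError("mapping file needs two columns: cell, subline")
    cell_col, sub_col = mapping.columns[:2]
    cell_to_subline = dict(zip(mapping[cell_col].astype(str), mapping[sub_col].astype(str)))
    ds = ExpressionDataset(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        cell_to_subline=cell_to_subline,
    )
    if tree is not None:
        ds.validate_against_tree(tree)
    return ds


def filter_genes(
    dataset: ExpressionDataset,
    min_expressed_fraction: float = 0.5,
) -> tuple[ExpressionDataset, list[str]]:
    """Drop genes expressed (> 0) in fewer than a fraction of cells, or constant.

    Returns the filtered dataset and the list of dropped gene ids.
    """
    frac = (dataset.values > 0).mean(axis=1)
    var = dataset.values.var(axis=1)
    keep = (frac >= min_expressed_fraction) & (var > 0)
    dropped = [g for g, k in zip(dataset.genes, keep) if not k]
    kept = ExpressionDataset(
        genes=[g for g, k in zip(dataset.genes, keep) if k],
        cells=list(dataset.cells),
        values=dataset.values[keep],
        cell_to_subline=dict(dataset.cell_to_subline),
    )
    return kept, dropped
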