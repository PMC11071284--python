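"""Simulate a labeled validation dataset on the 23-subline fixture tree.

Writes a reduced default-grid dataset (BM neutral genes plus two-optima
adaptive genes across optima-gap x selection-strength x noise
conditions, 8 cells per subline, TPM-like scale) under
results/simulated/, together with the tree and the ground-truth table.
"""

from pathlib import Path

from clonadapt.phylo import paint_regime
from clonadapt.synthetic import (
    FIXTURE_NEWICK,
    FIXTURE_REGIMES,
    default_grid,
    fixture_tree,
    make_grid_dataset,
)

SEED = 20240
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    tree = fixture_tree()
    painting = paint_regime(tree, set(FIXTURE_REGIMES["HA-R"]))
    grid = default_grid(replicates=(8,), n_genes=10)
    lab = make_grid_dataset(tree, painting, grid, seed=SEED, scale="tpm-like")
    OUT.mkdir(parents=True, exist_ok=True)
    lab.write(OUT / "expression.tsv", OUT / "cells.tsv", OUT / "truth.tsv")
    (OUT / "tree.nwk").write_text(FIXTURE_NEWICK + "\n")
    counts = lab.truth["label"].value_counts().to_dict()
    print(f"wrote {lab.dataset.n_genes} genes x {lab.dataset.n_cells} cells to {OUT}")
    print(f"labels: {counts}")


if __name__ == "__main__":
    main()
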