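"""Validation study: OU scan vs naive differential expression on simulations.

Simulates neutral BM genes across the replicate-noise grid and strongly
adaptive two-optima genes on the fixture tree, scans both with the
BM/OU1/OU2 likelihood machinery at BH-FDR 0.05, and benchmarks the
chosen-clade-vs-background Welch t-test on the same data.  The expected
picture: the scan holds its false-positive rate near or below the FDR
target while the t-test — blind to phylogenetic correlation — over-calls
neutral genes by an order of magnitude; under strong signal the scan
recovers essentially all adaptive genes.

Writes results/validation_metrics.json and results/validation_conditions.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from clonadapt.pipeline import STRONGEST_ADAPTIVE, neutral_grid, run_simulation_study

SEED = 20240
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    neutral = run_simulation_study(neutral_grid(n_per_condition=60), seed=SEED)
    power = run_simulation_study([STRONGEST_ADAPTIVE], seed=SEED)

    metrics = {
        "neutral_genes": neutral.n_neutral,
        "scan_false_positive_pct": round(neutral.scan_fpr_pct, 2),
        "ttest_false_positive_pct": round(neutral.de_fpr_pct, 2),
        "adaptive_genes_strongest_condition": power.n_adaptive,
        "scan_power_strongest_pct": round(power.scan_power_pct, 2),
        "ttest_power_strongest_pct": round(power.de_power_pct, 2),
        "seed": SEED,
    }
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "validation_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    table = pd.concat([neutral.per_condition, power.per_condition], ignore_index=True)
    table.to_csv(OUT / "validation_conditions.tsv", sep="\t", index=False)

    print(json.dumps(metrics, indent=2))
    print(
        f"\nOn {neutral.n_neutral} neutral genes the scan called "
        f"{metrics['scan_false_positive_pct']}% adaptive while the t-test flagged "
        f"{metrics['ttest_false_positive_pct']}% — the comparator ignores shared "
        f"ancestry and mistakes neutral drift for group differences.\n"
        f"Under the strongest adaptive condition the scan recovered "
        f"{metrics['scan_power_strongest_pct']}% of truth-adaptive genes."
    )


if __name__ == "__main__":
    main()
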