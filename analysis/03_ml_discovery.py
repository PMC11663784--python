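"""Hypothesis-free ML track: derive and lock the expression classifier.

On the (batch-harmonized) merged discovery cohort: quality control,
balanced downsampling iterations, robust two-test DEG selection, DMG
pruning, and the 12-configuration tournament (six algorithm families x
{all robust DEGs, DMG subset}); the winner is refit on all discovery
samples and locked.

Writes: results/03_deg_summary.tsv, results/03_cv_table.tsv,
        results/03_locked_model.json
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from radsig.discovery import (
    balance_iterations,
    quality_check,
    robust_genes,
    select_degs,
    select_dmgs,
    train_and_select,
)
from radsig.io import save_model
from radsig.pipeline import harmonize_discovery, simulate_study_split
from radsig.simulate import SimulationConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_ITER = 20  # balanced subsets; enough for a stable intersection at this n
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(effect_size_sd_units=1.5, seed=SEED)
    data = simulate_study_split(cfg)
    expr_d, qc_report = quality_check(data.expr_discovery.values)
    samples_d = data.samples_discovery.aligned_to(expr_d.sample_ids)
    print(f"QC: dropped {len(qc_report.dropped_genes)} genes, "
          f"{len(qc_report.dropped_samples)} samples")
    expr_d = harmonize_discovery(expr_d, samples_d)

    subsets = balance_iterations(samples_d, n_iter=N_ITER, seed=SEED)
    degs = select_degs(expr_d, samples_d, subsets)
    rob = robust_genes(degs)
    planted = set(data.truth["discovery_a"].planted_up) | set(data.truth["discovery_a"].planted_down)
    print(f"robust DEGs: {len(rob)} (of which planted: {len(set(rob) & planted)})")
    pd.DataFrame([asdict(d) | {"robust": d.robust} for d in degs]).query("robust").to_csv(
        OUT / "03_deg_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )

    dmgs = select_dmgs(expr_d, samples_d, rob, seed=SEED)
    print(f"DMG subset: {len(dmgs)} genes")

    cv_results, model = train_and_select(expr_d, samples_d, rob, dmgs, seed=SEED)
    cv = pd.DataFrame([asdict(c) for c in cv_results]).sort_values(
        "mean_accuracy", ascending=False)
    cv.to_csv(OUT / "03_cv_table.tsv", sep="\t", index=False, float_format="%.6g")
    print("\ncross-validation tournament:")
    print(cv[["config_id", "mean_accuracy", "n_genes"]].to_string(index=False))
    print(f"\nlocked: {model.algorithm_id} on {len(model.gene_list)} genes, "
          f"CV accuracy {model.cv_accuracy:.3f}, hash {model.hash()[:12]}")
    save_model(model, OUT / "03_locked_model.json")


if __name__ == "__main__":
    main()
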