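"""External validation of the locked model with both correction modes,
plus the random-geneset permutation null.

The locked model from the ML track is applied — never refit — to the
validation cohort after empirical-Bayes batch correction in supervised
(outcome-disclosing) and agnostic (outcome-blind) mode, and its gene list
is benchmarked against B size-matched random gene sets.

Writes: results/04_validation_reports.json, results/04_null_summary.json
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

from radsig.io import load_model
from radsig.pipeline import correct_validation, harmonize_discovery, simulate_study_split
from radsig.simulate import SimulationConfig
from radsig.validation import permutation_null, validate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
B = 200  # null draws; the minimum attainable p is 1/(B+1)
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    model = load_model(OUT / "03_locked_model.json")
    cfg = SimulationConfig(effect_size_sd_units=1.5, seed=SEED)
    data = simulate_study_split(cfg)
    expr_d = harmonize_discovery(data.expr_discovery, data.samples_discovery)

    reports = {}
    for mode in ("supervised", "agnostic"):
        expr_v = correct_validation(expr_d, data.samples_discovery,
                                    data.expr_validation, data.samples_validation, mode)
        rep = validate(model, expr_v, data.samples_validation, correction_mode=mode)
        reports[mode] = asdict(rep)
        print(f"{mode:>10}: accuracy {rep.accuracy:.3f}, sensitivity {rep.sensitivity:.3f}, "
              f"specificity {rep.specificity:.3f}, AUC {rep.auc:.3f} "
              f"[{rep.auc_ci[0]:.3f}, {rep.auc_ci[1]:.3f}]")

    # permutation null against the supervised-corrected validation cohort
    expr_v = correct_validation(expr_d, data.samples_discovery,
                                data.expr_validation, data.samples_validation, "supervised")
    obs = reports["supervised"]["auc"]
    null, p = permutation_null(
        expr_d, data.samples_discovery, expr_v, data.samples_validation,
        m=len(model.gene_list), B=B, observed_auc=obs, seed=SEED, mode="refit",
    )
    print(f"\npermutation null (B={B}, m={null.set_size}): "
          f"mean AUC {null.aucs.mean():.3f}, observed {obs:.3f}, p={p['p']:.4g}")
    with open(OUT / "04_validation_reports.json", "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
    with open(OUT / "04_null_summary.json", "w") as fh:
        json.dump({"B": B, "set_size": null.set_size,
                   "null_auc_mean": float(null.aucs.mean()),
                   "null_auc_q95": float(np.quantile(null.aucs, 0.95)),
                   "observed_auc": obs, **p}, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
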