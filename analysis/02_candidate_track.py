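"""Hypothesis-based candidate track on the synthetic study.

Scores candidate signatures on the merged discovery cohort (the planted
immune and stromal blocks play the role of the curated candidates such as
cytotoxic-lymphocyte and F-TBRS signatures; random-gene signatures act as
the unrelated candidates), then runs adjusted univariable logistic
regression, backward stepwise selection, the compound biology score, its
ROC, a likelihood-ratio test against the stage-only model, and per-cohort
meta-analysis of the retained features.

Writes: results/02_univariable.tsv, results/02_stepwise.json,
        results/02_meta_analysis.tsv
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from radsig.candidates import (
    backward_stepwise,
    compound_score,
    likelihood_ratio_test,
    meta_analyse,
    roc_auc,
    univariable_adjusted,
    _fit_logit,
    design_matrix,
)
from radsig.features import score_signature
from radsig.io import SignatureDef
from radsig.pipeline import simulate_study_split
from radsig.simulate import SimulationConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
ADJUST = ["cohort", "t_stage", "n_stage"]


def candidate_signatures(truth, gene_universe, rng) -> list[SignatureDef]:
    noise = [g for g in gene_universe
             if g not in set(truth.planted_up) | set(truth.planted_down)]
    picks = rng.choice(noise, size=60, replace=False)
    return [
        SignatureDef("immune_cytotoxic", truth.planted_up),
        SignatureDef("stromal_tgfb", truth.planted_down),
        SignatureDef("unrelated_a", list(picks[:20])),
        SignatureDef("unrelated_b", list(picks[20:40])),
        SignatureDef("unrelated_c", list(picks[40:60])),
    ]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(effect_size_sd_units=1.5, seed=SEED)
    data = simulate_study_split(cfg)
    truth = data.truth["discovery_a"]
    rng = np.random.default_rng(SEED)
    sigs = candidate_signatures(truth, data.expr_discovery.gene_ids, rng)

    scores_d = pd.DataFrame({s.name: score_signature(data.expr_discovery, s) for s in sigs})
    rows = []
    for name in scores_d.columns:
        r = univariable_adjusted(scores_d[name], data.samples_discovery, ADJUST)
        rows.append({"feature": name, "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "p_value": r.p_value, "n": r.n_used})
    uni = pd.DataFrame(rows)
    uni.to_csv(OUT / "02_univariable.tsv", sep="\t", index=False, float_format="%.6g")
    print("adjusted univariable results (discovery):")
    print(uni.to_string(index=False))

    model = backward_stepwise(scores_d, data.samples_discovery, ADJUST, alpha_remove=0.05)
    print(f"\nstepwise retained: {model.retained} "
          f"(removed: {[t[0] for t in model.trace]})")

    comp = compound_score(model, scores_d)
    y_d = data.samples_discovery.aligned_to(list(comp.index)).pcr_vector()
    auc_d = roc_auc(comp.to_numpy(), y_d).auc

    # does the compound add to a stage-only model?
    t = data.samples_discovery.table.set_index("sample_id")
    cov = design_matrix(data.samples_discovery, ADJUST).set_index(t.index)
    null_res, _ = _fit_logit(t["pcr"].to_numpy(float), cov)
    full_res, _ = _fit_logit(t["pcr"].to_numpy(float), cov.assign(compound=comp))
    lrt_stat, lrt_df, lrt_p = likelihood_ratio_test(null_res, full_res)
    print(f"compound score AUC (discovery): {auc_d:.3f}; "
          f"LRT vs stage model: chi2={lrt_stat:.2f}, df={lrt_df}, p={lrt_p:.2e}")

    # per-cohort meta-analysis of each retained feature
    from radsig.simulate import simulate_cohort

    meta_rows = []
    for feat in model.retained:
        betas, ses = [], []
        for cohort in cfg.cohort_sizes:
            expr_c, samples_c, _ = simulate_cohort(cfg, cohort)
            sig = next(s for s in sigs if s.name == feat)
            sc = score_signature(expr_c, sig)
            r = univariable_adjusted(sc, samples_c, ["t_stage", "n_stage"])
            betas.append(r.beta)
            ses.append(r.se)
        m = meta_analyse(betas, ses, feature=feat)
        meta_rows.append({"feature": feat, "pooled_log_or": m.pooled_beta,
                          "pooled_se": m.pooled_se, "pooled_p": m.pooled_p,
                          "Q": m.q, "I2": m.i2})
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(OUT / "02_meta_analysis.tsv", sep="\t", index=False, float_format="%.6g")
    print("\ncross-cohort meta-analysis of retained features:")
    print(meta.to_string(index=False))

    with open(OUT / "02_stepwise.json", "w") as fh:
        json.dump({"retained": model.retained, "coefficients": model.coefficients,
                   "intercept": model.intercept, "compound_auc_discovery": auc_d,
                   "lrt_vs_stage": {"stat": lrt_stat, "df": lrt_df, "p": lrt_p}},
                  fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
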