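"""Biological characterization of the locked model.

Preranked GSEA of the predicted-status and actual-status contrasts on the
validation cohort over hallmark-style gene sets (the planted immune and
stromal blocks plus random sets), their concordance; per-gene regression
of locked-model genes against the candidate biology scores meta-analysed
across cohorts; and cell-type specificity of the model genes against a
synthetic sorted-population reference.

Writes: results/05_enrichment.tsv, results/05_concordance.json,
        results/05_gene_feature_meta.tsv, results/05_cell_types.tsv
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from radsig.biology import (
    assign_cell_types,
    concordance_of_contrasts,
    gene_feature_meta,
    gsea_preranked,
    rank_genes,
)
from radsig.features import score_signature
from radsig.io import GeneSetCollection, SignatureDef, load_model
from radsig.pipeline import correct_validation, harmonize_discovery, simulate_study_split
from radsig.simulate import SimulationConfig, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def hallmark_like_sets(truth, gene_universe, rng) -> GeneSetCollection:
    noise = [g for g in gene_universe
             if g not in set(truth.planted_up) | set(truth.planted_down)]
    sets = {"INTERFERON_LIKE_IMMUNE": truth.planted_up,
            "EMT_LIKE_STROMAL": truth.planted_down}
    for i in range(8):
        sets[f"RANDOM_HALLMARK_{i}"] = list(rng.choice(noise, size=30, replace=False))
    return GeneSetCollection(sets)


def synthetic_cell_reference(genes, truth, rng) -> pd.DataFrame:
    """Synthetic stand-in for a FACS-sorted four-population expression
    reference: immune-block genes enriched in leucocytes, stromal-block
    genes in fibroblasts, the rest unspecific."""
    base = rng.lognormal(3, 0.2, size=(len(genes), 4))
    ref = pd.DataFrame(base, index=genes,
                       columns=["epithelial", "leucocyte", "endothelial", "fibroblast"])
    ref.loc[[g for g in truth.planted_up if g in ref.index], "leucocyte"] *= 4
    ref.loc[[g for g in truth.planted_down if g in ref.index], "fibroblast"] *= 4
    return ref


def main() -> None:
    OUT.mkdir(exist_ok=True)
    model = load_model(OUT / "03_locked_model.json")
    cfg = SimulationConfig(effect_size_sd_units=1.5, seed=SEED)
    data = simulate_study_split(cfg)
    truth = data.truth["discovery_a"]
    rng = np.random.default_rng(SEED + 1)
    expr_d = harmonize_discovery(data.expr_discovery, data.samples_discovery)
    expr_v = correct_validation(expr_d, data.samples_discovery,
                                data.expr_validation, data.samples_validation, "supervised")

    y_true = data.samples_validation.aligned_to(expr_v.sample_ids).pcr_vector()
    scores = model.predict_scores(expr_v)
    y_pred = (scores >= 0.5).astype(int)
    sets = hallmark_like_sets(truth, expr_v.gene_ids, rng)
    enrich_pred = gsea_preranked(rank_genes(expr_v, y_pred), sets, n_perm=500, seed=SEED)
    enrich_true = gsea_preranked(rank_genes(expr_v, y_true), sets, n_perm=500, seed=SEED)
    table = pd.DataFrame(
        [{"contrast": c, "set": r.set_name, "es": r.es, "nes": r.nes,
          "p": r.p_value, "fdr": r.fdr, "direction": r.direction}
         for c, rr in (("predicted", enrich_pred), ("actual", enrich_true)) for r in rr])
    table.to_csv(OUT / "05_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    conc = concordance_of_contrasts(enrich_pred, enrich_true, fdr_cut=0.25)
    print("enrichment concordance (predicted vs actual status):")
    print(f"  shared significant sets: {conc['shared']}")
    print(f"  sign agreement: {conc['sign_agreement']:.0%}")
    with open(OUT / "05_concordance.json", "w") as fh:
        json.dump(conc, fh, indent=1, sort_keys=True)

    # per-gene association of model genes with the two biology scores
    exprs, feats = {}, {}
    for cohort in cfg.cohort_sizes:
        expr_c, _, _ = simulate_cohort(cfg, cohort)
        feats[cohort] = pd.DataFrame({
            "immune_cytotoxic": score_signature(expr_c, SignatureDef("i", truth.planted_up)),
            "stromal_tgfb": score_signature(expr_c, SignatureDef("s", truth.planted_down)),
        })
        exprs[cohort] = expr_c
    meta = gene_feature_meta(exprs, feats, model.gene_list)
    meta_table = pd.DataFrame(
        [{"gene": g, "feature": f, "pooled_beta": m.pooled_beta, "pooled_se": m.pooled_se,
          "pooled_p": m.pooled_p, "I2": m.i2} for (g, f), m in meta.items()])
    meta_table.to_csv(OUT / "05_gene_feature_meta.tsv", sep="\t", index=False,
                      float_format="%.6g")
    n_immune = (meta_table.query("feature == 'immune_cytotoxic' and pooled_p < 0.05")
                ["pooled_beta"] > 0).sum()
    print(f"\nmodel genes positively tracking the immune score: {n_immune} "
          f"of {len(model.gene_list)}")

    ref = synthetic_cell_reference(expr_v.gene_ids, truth, rng)
    assigns = assign_cell_types(ref, model.gene_list)
    ct = pd.DataFrame([{"gene": a.gene, "cell_type": a.assigned,
                        "fold_change": a.fold_change} for a in assigns])
    ct.to_csv(OUT / "05_cell_types.tsv", sep="\t", index=False, float_format="%.4g")
    specific = (ct["cell_type"] != "none").sum()
    print(f"cell-type-specific model genes: {specific} of {len(ct)}")


if __name__ == "__main__":
    main()
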