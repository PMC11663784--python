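"""End-to-end workflows tying the stages together.

The canonical flow mirrors the study design: merge the two discovery
cohorts, harmonize their batches, derive a locked model on discovery only,
then batch-correct the external validation cohort against the (frozen)
discovery data — in supervised (outcome-disclosing) or agnostic
(outcome-blind) mode — and apply the locked model without refitting.
Validation data never enters model derivation, so the locked model is
identical whichever correction mode is evaluated afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .combat import apply_combat, fit_combat
from .discovery import balance_iterations, robust_genes, select_degs
from .io import ExpressionMatrix, LockedModel, SampleTable
from .simulate import SimulationConfig, merge_cohorts, simulate_study
from .validation import ValidationReport, validate

logger = logging.getLogger("radsig")


@dataclass
class StudyData:
    expr_discovery: ExpressionMatrix
    samples_discovery: SampleTable
    expr_validation: ExpressionMatrix
    samples_validation: SampleTable
    truth: dict


def simulate_study_split(cfg: SimulationConfig) -> StudyData:
    """Simulate all cohorts and merge the non-validation ones into the
    discovery set, relabelled as one pooled discovery cohort."""
    study = simulate_study(cfg)
    discovery_parts = [(e, s) for name, (e, s, _) in study.items() if name != "validation"]
    expr_d, samples_d = merge_cohorts(discovery_parts)
    expr_v, samples_v, _ = study["validation"]
    return StudyData(expr_d, samples_d, expr_v, samples_v,
                     {name: t for name, (_, _, t) in study.items()})


def harmonize_discovery(
    expr_d: ExpressionMatrix, samples_d: SampleTable
) -> ExpressionMatrix:
    """Remove the within-discovery cohort batch effects (outcomes are
    known at discovery time, so the supervised design is used)."""
    if samples_d.table["batch"].nunique() < 2:
        return expr_d
    model = fit_combat(expr_d, samples_d, mode="supervised")
    return apply_combat(model, expr_d, samples_d)


def lean_locked_model(
    expr_d: ExpressionMatrix,
    samples_d: SampleTable,
    seed: int,
    n_iter: int = 10,
    alpha_adj: float = 0.05,
    fallback_top: int = 40,
) -> LockedModel:
    """Robust-DEG selection plus an L1-logistic lock.

    The fast single-algorithm counterpart of the full tournament for
    experiments that only need one frozen model per run; if no gene
    survives every balanced subset, the top genes by median adjusted p
    are used instead (logged)."""
    subsets = balance_iterations(samples_d, n_iter=n_iter, seed=seed)
    degs = select_degs(expr_d, samples_d, subsets, alpha_adj=alpha_adj)
    genes = robust_genes(degs)
    if not genes:
        ranked = sorted(degs, key=lambda d: d.median_adj_p_modt)
        genes = [d.gene for d in ranked[:fallback_top]]
        logger.warning("no robust DEG; falling back to top %d by median adjusted p", len(genes))
    est = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, random_state=seed)),
    ])
    est.fit(expr_d.values.loc[genes].to_numpy().T, samples_d.pcr_vector())
    return LockedModel(
        algorithm_id="lasso",
        gene_list=genes,
        hyperparameters={"C": 1.0, "penalty": "l1"},
        estimator=est,
        training_seed=seed,
        created_from="lean_locked_model",
    )


def correct_validation(
    expr_d: ExpressionMatrix,
    samples_d: SampleTable,
    expr_v: ExpressionMatrix,
    samples_v: SampleTable,
    mode: str,
) -> ExpressionMatrix:
    """Batch-correct the validation cohort against discovery.

    Discovery and validation are merged under two batch labels, the EB
    model is fitted in the requested mode, and only the corrected
    validation columns are returned; discovery data stay frozen."""
    td = samples_d.table.copy()
    td["batch"] = "discovery"
    tv = samples_v.table.copy()
    tv["batch"] = "validation"
    combined_samples = SampleTable(pd.concat([td, tv], ignore_index=True))
    combined_expr = ExpressionMatrix(pd.concat([expr_d.values, expr_v.values], axis=1))
    model = fit_combat(combined_expr, combined_samples, mode=mode)
    corrected = apply_combat(model, combined_expr, combined_samples)
    return corrected.subset_samples(expr_v.sample_ids)


def run_locked_validation(
    cfg: SimulationConfig,
    seed: int,
    n_iter: int = 10,
    threshold: float = 0.5,
) -> dict[str, ValidationReport]:
    """Full lean pipeline on one simulated study: returns the validation
    report under each correction mode, sharing one locked model."""
    cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    data = simulate_study_split(cfg)
    expr_d = harmonize_discovery(data.expr_discovery, data.samples_discovery)
    model = lean_locked_model(expr_d, data.samples_discovery, seed=seed, n_iter=n_iter)
    out = {}
    for mode in ("supervised", "agnostic"):
        expr_v_corr = correct_validation(
            expr_d, data.samples_discovery, data.expr_validation, data.samples_validation, mode
        )
        out[mode] = validate(model, expr_v_corr, data.samples_validation,
                             threshold=threshold, correction_mode=mode)
    assert out["supervised"].model_hash == out["agnostic"].model_hash
    return out
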