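"""External validation of a locked predictor.

Applies a frozen model to a (batch-corrected) validation cohort without
refitting — the model payload is fingerprinted before and after — and
reports confusion counts, sensitivity/specificity/accuracy, and AUC with a
DeLong confidence interval. A random-geneset permutation null puts the
model's gene list in context: B size-matched random sets are drawn from
the QC-passing universe, each run through the same learner recipe on the
discovery cohort (or scored directly in the cheaper score-only mode), and
the observed validation AUC is ranked against the null AUCs with the
add-one convention p = (r + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .candidates import roc_auc, univariable_adjusted
from .features import ScoringError, score_signature
from .io import ExpressionMatrix, LockedModel, SampleTable, SignatureDef, ValidationError

logger = logging.getLogger("radsig")


@dataclass
class ValidationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    model_hash: str
    correction_mode: str = ""
    permutation_p: float = float("nan")


@dataclass
class NullDistribution:
    aucs: np.ndarray
    set_size: int
    universe_size: int
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.aucs)


def delong_ci(score, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC and DeLong (1988) confidence interval from placement values."""
    score = np.asarray(score, float)
    labels = np.asarray(labels, int)
    pos, neg = score[labels == 1], score[labels == 0]
    n1, n0 = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n0 for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n1 for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_metrics(calls: np.ndarray, labels: np.ndarray) -> dict:
    calls = np.asarray(calls, int)
    labels = np.asarray(labels, int)
    tp = int(((calls == 1) & (labels == 1)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(labels) if len(labels) else float("nan"),
    }


def validate(
    model: LockedModel,
    expr_corrected: ExpressionMatrix,
    samples: SampleTable,
    threshold: float = 0.5,
    correction_mode: str = "",
) -> ValidationReport:
    """Apply a locked model to a validation cohort; never refits."""
    hash_before = model.hash()
    samples = samples.aligned_to(expr_corrected.sample_ids)
    y = samples.pcr_vector()
    scores = model.predict_scores(expr_corrected)
    assert model.hash() == hash_before, "locked model mutated during prediction"
    calls = (scores >= threshold).astype(int)
    m = confusion_metrics(calls, y)
    if len(np.unique(y)) < 2:
        logger.warning("one outcome class absent; AUC not computable")
        auc, lo, hi = float("nan"), float("nan"), float("nan")
    else:
        auc, lo, hi = delong_ci(scores, y)
    return ValidationReport(
        tp=m["tp"], fp=m["fp"], tn=m["tn"], fn=m["fn"],
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        accuracy=m["accuracy"], auc=auc, auc_ci=(lo, hi),
        threshold=threshold, model_hash=hash_before,
        correction_mode=correction_mode,
    )


def default_learner_recipe(seed: int):
    """The learner refit on each random gene set: scaled L1 logistic."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, random_state=seed)),
    ])


def permutation_null(
    expr_discovery: ExpressionMatrix,
    samples_discovery: SampleTable,
    expr_validation: ExpressionMatrix,
    samples_validation: SampleTable,
    m: int,
    B: int,
    observed_auc: float | None = None,
    universe: list[str] | None = None,
    seed: int = 0,
    learner_recipe=default_learner_recipe,
    mode: str = "refit",
) -> tuple[NullDistribution, dict]:
    """Empirical null over B random gene sets of size m.

    ``mode='refit'`` fits the learner recipe on discovery per draw and
    scores validation; ``mode='score_only'`` scores validation directly by
    the mean z-score of the drawn genes (cheap screen). Returns the null
    and a dict with p-values under both tie conventions:
    ``p`` = (#{null >= observed} + 1)/(B + 1) and ``p_strict`` using >.
    """
    universe = list(universe) if universe is not None else list(expr_discovery.gene_ids)
    universe = [g for g in universe if g in expr_validation.values.index]
    if m > len(universe):
        raise ValueError(f"set size {m} exceeds universe of {len(universe)} genes")
    rng = np.random.default_rng(seed)
    y_disc = samples_discovery.aligned_to(expr_discovery.sample_ids).pcr_vector()
    y_val = samples_validation.aligned_to(expr_validation.sample_ids).pcr_vector()
    aucs = np.empty(B)
    for b in range(B):
        genes = list(rng.choice(universe, size=m, replace=False))
        if mode == "refit":
            est = learner_recipe(seed)
            est.fit(expr_discovery.values.loc[genes].to_numpy().T, y_disc)
            Xv = expr_validation.values.loc[genes].to_numpy().T
            s = est.predict_proba(Xv)[:, 1] if hasattr(est, "predict_proba") else est.decision_function(Xv)
        elif mode == "score_only":
            s = score_signature(expr_validation, SignatureDef(f"null_{b}", genes)).to_numpy()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        aucs[b] = roc_auc(s, y_val).auc
    null = NullDistribution(aucs=aucs, set_size=m, universe_size=len(universe), seed=seed)
    pvals = {}
    if observed_auc is not None:
        r = int((aucs >= observed_auc).sum())
        pvals["p"] = (r + 1) / (B + 1)
        pvals["p_strict"] = (int((aucs > observed_auc).sum()) + 1) / (B + 1)
    return null, pvals


def compare_signatures(
    signatures: list[SignatureDef],
    expr_corrected: ExpressionMatrix,
    samples: SampleTable,
    adjust: list[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark published signatures on one cohort.

    Returns (Pearson correlation matrix of per-sample scores, per-signature
    table with adjusted logistic OR/p and AUC, sorted by AUC descending).
    Unscorable signatures are excluded with a warning.
    """
    samples = samples.aligned_to(expr_corrected.sample_ids)
    y = samples.pcr_vector()
    scored: dict[str, pd.Series] = {}
    for sig in signatures:
        try:
            method = "weighted_sum" if sig.weights is not None else "mean_z"
            scored[sig.name] = score_signature(expr_corrected, sig, method=method)
        except ScoringError as exc:
            logger.warning("signature %r excluded: %s", sig.name, exc)
    if not scored:
        raise ValidationError("no scorable signature")
    frame = pd.DataFrame(scored)
    corr = frame.corr(method="pearson")
    rows = []
    for name in frame.columns:
        res = univariable_adjusted(frame[name], samples, adjust)
        auc = roc_auc(frame[name].to_numpy(), y).auc
        rows.append({
            "signature": name, "odds_ratio": res.odds_ratio, "p_value": res.p_value,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "auc": auc,
        })
    table = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    return corr, table
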