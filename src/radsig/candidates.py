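"""Hypothesis-based candidate track.

Adjusted univariable logistic regression for each candidate feature,
backward stepwise multivariable selection by likelihood-ratio p-value, the
compound biological radiosensitivity score (linear predictor restricted to
the biology terms), ROC/AUC, likelihood-ratio testing of nested models,
and inverse-variance fixed/random-effects meta-analysis with Cochran Q and
I-squared heterogeneity.

Adjustment covariates follow the study convention: cohort as a dummy-coded
categorical, baseline T and N stage as ordinal numeric by default
(``stage_encoding='categorical'`` switches to dummies).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import SampleTable
from .features import ScoreTable

logger = logging.getLogger("radsig")

SEPARATION_BETA_BOUND = 15.0  # |log OR| beyond this on standardized-ish data: separation


@dataclass
class CandidateResult:
    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjusted_for: list[str]
    beta: float = float("nan")
    se: float = float("nan")
    separation_flag: bool = False


@dataclass
class StepwiseModel:
    retained: list[str]
    coefficients: dict[str, float]
    intercept: float
    log_likelihood: float
    trace: list[tuple[str, float, int]]  # (feature removed, LR p, step)
    adjusted_for: list[str] = field(default_factory=list)


@dataclass
class MetaResult:
    feature: str
    betas: list[float]
    ses: list[float]
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    q: float
    i2: float
    re_pooled_beta: float | None = None
    re_pooled_se: float | None = None
    tau2: float | None = None


def design_matrix(
    samples: SampleTable, adjust: list[str], stage_encoding: str = "ordinal"
) -> pd.DataFrame:
    """Covariate design (no intercept column) for the requested adjustment."""
    t = samples.table
    parts = []
    for cov in adjust:
        if cov in ("cohort", "batch"):
            d = pd.get_dummies(t[cov].astype(str), prefix=cov, drop_first=True, dtype=float)
            parts.append(d)
        elif cov in ("t_stage", "n_stage"):
            if stage_encoding == "ordinal":
                parts.append(t[cov].astype(float).rename(cov))
            elif stage_encoding == "categorical":
                parts.append(
                    pd.get_dummies(t[cov].astype("Int64").astype(str), prefix=cov, drop_first=True, dtype=float)
                )
            else:
                raise ValueError(f"unknown stage_encoding {stage_encoding!r}")
        else:
            parts.append(t[cov].astype(float).rename(cov))
    if not parts:
        return pd.DataFrame(index=t.index)
    return pd.concat(parts, axis=1)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Maximum-likelihood logistic fit; returns the statsmodels result and
    a separation flag."""
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            # retry with a more forgiving optimizer before declaring separation
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=500, method="bfgs")
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params[1:]).max(initial=0) > SEPARATION_BETA_BOUND:
        separated = True
    return res, separated


def univariable_adjusted(
    score: pd.Series,
    samples: SampleTable,
    adjust: list[str] = (),
    stage_encoding: str = "ordinal",
) -> CandidateResult:
    """Adjusted univariable logistic regression of pCR on one feature.

    Complete-case over outcome, feature and covariates; perfect separation
    is flagged (infinite-OR sentinel) rather than silently penalized.
    """
    t = samples.table.set_index("sample_id")
    score = score.reindex(t.index)
    cov = design_matrix(samples, list(adjust), stage_encoding).set_index(t.index)
    frame = pd.concat([t["pcr"], score.rename("_score"), cov], axis=1)
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.info("univariable %s: %d rows dropped (complete-case)", score.name, dropped)
    y = frame["pcr"].to_numpy(float)
    if frame["_score"].nunique() <= 1:
        raise ValueError(f"feature {score.name!r} is constant; cannot fit")
    if int(y.sum()) < 10:
        logger.warning("univariable %s: only %d events", score.name, int(y.sum()))
    X = frame.drop(columns=["pcr"])
    res, separated = _fit_logit(y, X)
    beta = float(res.params["_score"])
    se = float(res.bse["_score"])
    if separated:
        sign = np.sign(beta) if beta != 0 else 1.0
        return CandidateResult(
            feature=str(score.name),
            odds_ratio=float("inf") if sign > 0 else 0.0,
            ci_low=0.0,
            ci_high=float("inf"),
            p_value=1.0,
            n_used=len(frame),
            adjusted_for=list(adjust),
            beta=beta,
            se=se,
            separation_flag=True,
        )
    zcrit = stats.norm.ppf(0.975)
    return CandidateResult(
        feature=str(score.name),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        p_value=float(res.pvalues["_score"]),
        n_used=len(frame),
        adjusted_for=list(adjust),
        beta=beta,
        se=se,
    )


def likelihood_ratio_test(null_res, full_res) -> tuple[float, int, float]:
    """LR test of nested logistic fits: 2*(ll_full - ll_null) ~ chi2(df)."""
    null_names = set(null_res.model.exog_names)
    full_names = set(full_res.model.exog_names)
    if not null_names <= full_names:
        raise ValueError("models are not nested (null parameters not a subset)")
    if null_res.nobs != full_res.nobs:
        raise ValueError("models fit on different numbers of rows")
    statistic = max(0.0, 2.0 * (full_res.llf - null_res.llf))
    df = len(full_names) - len(null_names)
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    if statistic == 0.0:
        p = 1.0
    return float(statistic), int(df), p


def _stepwise_frame(
    scores: ScoreTable | pd.DataFrame, samples: SampleTable, adjust, stage_encoding
):
    frame = scores.scores if isinstance(scores, ScoreTable) else scores
    t = samples.table.set_index("sample_id")
    cov = design_matrix(samples, list(adjust), stage_encoding).set_index(t.index)
    full = pd.concat([t["pcr"], frame.reindex(t.index), cov], axis=1).dropna()
    y = full["pcr"].to_numpy(float)
    features = list(frame.columns)
    cov_cols = list(cov.columns)
    return y, full, features, cov_cols


def backward_stepwise(
    scores: ScoreTable | pd.DataFrame,
    samples: SampleTable,
    adjust: list[str] = (),
    alpha_remove: float = 0.05,
    stage_encoding: str = "ordinal",
) -> StepwiseModel:
    """Backward stepwise multivariable logistic selection.

    At each step, each remaining feature is tested by a likelihood-ratio
    test against the model without it; the feature with the largest LR
    p-value is removed while that p exceeds ``alpha_remove``. Adjustment
    covariates are forced (never removed). Ties break by column order.
    """
    y, full, features, cov_cols = _stepwise_frame(scores, samples, adjust, stage_encoding)
    current = list(features)
    trace: list[tuple[str, float, int]] = []
    step = 0
    while current:
        full_res, _ = _fit_logit(y, full[current + cov_cols])
        worst_feature, worst_p = None, -1.0
        for f in current:
            reduced = [c for c in current if c != f]
            null_res, _ = _fit_logit(y, full[reduced + cov_cols])
            _, _, p = likelihood_ratio_test(null_res, full_res)
            if p > worst_p:  # strict > keeps first (column-order) on ties
                worst_feature, worst_p = f, p
        if worst_p > alpha_remove:
            step += 1
            trace.append((worst_feature, worst_p, step))
            current.remove(worst_feature)
            logger.info("stepwise: removed %s (LR p=%.4g)", worst_feature, worst_p)
        else:
            break
    if not current:
        logger.warning("stepwise: all features eliminated; empty model")
        return StepwiseModel([], {}, 0.0, float("nan"), trace, list(adjust))
    final_res, _ = _fit_logit(y, full[current + cov_cols])
    coefs = {f: float(final_res.params[f]) for f in current}
    return StepwiseModel(
        retained=current,
        coefficients=coefs,
        intercept=float(final_res.params["const"]),
        log_likelihood=float(final_res.llf),
        trace=trace,
        adjusted_for=list(adjust),
    )


def compound_score(model: StepwiseModel, scores: ScoreTable | pd.DataFrame) -> pd.Series:
    """Compound biology score: intercept + sum of beta_f * score_f over the
    retained features, excluding covariate terms — a monotone transform of
    the model probability restricted to biology."""
    frame = scores.scores if isinstance(scores, ScoreTable) else scores
    missing = [f for f in model.retained if f not in frame.columns]
    if missing:
        raise ValueError(f"score table lacks retained features: {missing}")
    out = pd.Series(model.intercept, index=frame.index, dtype=float)
    for f in model.retained:
        out = out + model.coefficients[f] * frame[f].astype(float)
    return out.rename("compound")


@dataclass
class RocCurve:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(score, labels) -> RocCurve:
    """AUC as the Mann-Whitney U statistic over n1*n0 pairs (ties count
    1/2), plus the ROC step points."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present for ROC")
    ranks = stats.rankdata(score)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thr = _sk_roc(labels, score)
    return RocCurve(float(auc), fpr, tpr, thr)


def meta_analyse(betas, ses, feature: str = "") -> MetaResult:
    """Fixed-effect inverse-variance pooling with Cochran Q and I2;
    DerSimonian-Laird random effects reported when k >= 2."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("meta-analysis needs at least one cohort")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float((w * betas).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    pooled_p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    k = betas.size
    if k == 1:
        return MetaResult(feature, list(betas), list(ses), pooled, pooled_se, pooled_p, 0.0, 0.0)
    q = float((w * (betas - pooled) ** 2).sum())
    df = k - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_re = 1.0 / (ses**2 + tau2)
    re_pooled = float((w_re * betas).sum() / w_re.sum())
    re_se = float(1.0 / np.sqrt(w_re.sum()))
    return MetaResult(
        feature, list(betas), list(ses), pooled, pooled_se, pooled_p, q, i2,
        re_pooled_beta=re_pooled, re_pooled_se=re_se, tau2=float(tau2),
    )
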