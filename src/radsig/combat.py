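"""Parametric empirical-Bayes location/scale batch adjustment (ComBat).

Model per gene g, batch b, sample j:

    x_gbj = alpha_g + X_j beta_g + gamma_gb + delta_gb * eps_gbj

After standardizing each gene by its covariate-adjusted grand mean and
pooled variance, per-batch location (gamma) and scale (delta) estimates are
shrunk toward their across-gene priors — normal for locations,
inverse-gamma for scales, hyperparameters by method of moments — via the
standard fixed-point iteration, then removed.

Two covariate designs are supported. ``supervised`` discloses the outcome
(pCR) to the correction so merging cohorts does not erase the outcome
signal; ``agnostic`` is outcome-blind — the deliberately suboptimal but
leakage-free alternative. The mode is recorded in the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleTable, ValidationError

logger = logging.getLogger("radsig")


class BatchError(ValueError):
    pass


@dataclass
class CorrectionModel:
    mode: str
    batches: list[str]
    n_per_batch: dict[str, int]
    grand_mean: pd.Series  # per gene
    var_pooled: pd.Series  # per gene
    gamma_star: pd.DataFrame  # genes x batches (EB-shrunk locations)
    delta_star: pd.DataFrame  # genes x batches (EB-shrunk scales, > 0)
    covariates: list[str]
    mod_columns: list[str]
    beta_mod: pd.DataFrame  # genes x mod columns
    n_iterations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.delta_star.to_numpy() <= 0).any():
            raise ValidationError("delta_star must be positive")


def _mod_design(samples: SampleTable, mode: str, covariates: list[str]) -> pd.DataFrame:
    """Non-batch covariate design; supervised mode prepends the outcome."""
    cols = (["pcr"] if mode == "supervised" else []) + [c for c in covariates if c != "pcr"]
    t = samples.table
    parts = []
    for c in cols:
        if c == "pcr":
            if t["pcr"].isna().any():
                raise BatchError("supervised correction requires pcr for every sample")
            parts.append(t["pcr"].astype(float).rename("pcr"))
        elif pd.api.types.is_numeric_dtype(t[c]):
            parts.append(t[c].astype(float).rename(c))
        else:
            parts.append(pd.get_dummies(t[c].astype(str), prefix=c, drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=t.index)
    return pd.concat(parts, axis=1)


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z_batch: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fixed-point iteration for the EB posterior location/scale of one batch."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs((g_new - g_old) / np.where(g_old == 0, 1.0, g_old)).max(),
            np.abs((d_new - d_old) / d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def fit_combat(
    expr: ExpressionMatrix,
    samples: SampleTable,
    mode: str = "supervised",
    covariates: list[str] = (),
    conv: float = 1e-6,
    max_iter: int = 1000,
) -> CorrectionModel:
    """Fit the EB correction on a combined (multi-batch) matrix.

    Requires >= 2 batches with >= 2 samples each; ``mode='supervised'``
    additionally requires pcr for all samples.
    """
    if mode not in ("supervised", "agnostic"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = samples.aligned_to(expr.sample_ids)
    batch = samples.table["batch"].astype(str)
    batches = list(pd.unique(batch))
    if len(batches) < 2:
        raise BatchError("batch correction needs >= 2 batches")
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise BatchError(f"batches with a single sample: {small}")

    X = expr.values.to_numpy()  # genes x samples
    genes = expr.values.index
    n_array = X.shape[1]
    batch_design = pd.get_dummies(batch, dtype=float)[batches].to_numpy()  # samples x B
    mod = _mod_design(samples, mode, list(covariates))
    design = np.hstack([batch_design, mod.to_numpy()]) if mod.shape[1] else batch_design

    # per-gene OLS of expression on [batch one-hots | covariates]
    B_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (B + p) x genes
    n_b = batch_design.sum(axis=0)
    grand_mean = (n_b / n_array) @ B_hat[: len(batches)]  # per gene
    resid = X - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if (var_pooled <= 0).any():
        raise BatchError("zero pooled variance for some genes; drop constant genes first")

    stand_mean = grand_mean[:, None] + (
        (mod.to_numpy() @ B_hat[len(batches):]).T if mod.shape[1] else 0.0
    )
    Z = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((X.shape[0], len(batches)))
    delta_star = np.empty_like(gamma_star)
    n_iterations = {}
    for k, b_name in enumerate(batches):
        mask = batch_design[:, k].astype(bool)
        zb = Z[:, mask]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, bp = _aprior(d_hat), _bprior(d_hat)
        g_s, d_s, its = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, bp, conv, max_iter)
        gamma_star[:, k], delta_star[:, k] = g_s, d_s
        n_iterations[b_name] = its
        logger.info("combat: batch %s converged in %d iterations", b_name, its)

    return CorrectionModel(
        mode=mode,
        batches=batches,
        n_per_batch={b: int(c) for b, c in counts.items()},
        grand_mean=pd.Series(grand_mean, index=genes),
        var_pooled=pd.Series(var_pooled, index=genes),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=batches),
        delta_star=pd.DataFrame(delta_star, index=genes, columns=batches),
        covariates=list(covariates),
        mod_columns=list(mod.columns),
        beta_mod=pd.DataFrame(B_hat[len(batches):].T, index=genes, columns=mod.columns),
        n_iterations=n_iterations,
    )


def _stand_mean_for(model: CorrectionModel, samples: SampleTable, genes) -> np.ndarray:
    mod = _mod_design(samples, model.mode, model.covariates)
    mod = mod.reindex(columns=model.mod_columns, fill_value=0.0)
    base = model.grand_mean.loc[genes].to_numpy()[:, None]
    if model.mod_columns:
        base = base + model.beta_mod.loc[genes].to_numpy() @ mod.to_numpy().T
    return base


def apply_combat(
    model: CorrectionModel, expr: ExpressionMatrix, samples: SampleTable
) -> ExpressionMatrix:
    """Remove the fitted batch effects from ``expr``.

    Every sample's batch label must be one the model was fitted on; genes
    must be a subset of the model's genes.
    """
    samples = samples.aligned_to(expr.sample_ids)
    batch = samples.table["batch"].astype(str)
    unknown = set(batch) - set(model.batches)
    if unknown:
        raise BatchError(f"unknown batch labels: {sorted(unknown)}")
    missing = [g for g in expr.values.index if g not in model.grand_mean.index]
    if missing:
        raise ValidationError(f"genes absent from correction model: {missing[:10]}")
    genes = expr.values.index
    X = expr.values.to_numpy()
    sm_ = _stand_mean_for(model, samples, genes)
    sp = np.sqrt(model.var_pooled.loc[genes].to_numpy())[:, None]
    Z = (X - sm_) / sp
    gam = model.gamma_star.loc[genes, list(batch)].to_numpy()
    del_ = model.delta_star.loc[genes, list(batch)].to_numpy()
    Z_adj = (Z - gam) / np.sqrt(del_)
    out = Z_adj * sp + sm_
    return ExpressionMatrix(pd.DataFrame(out, index=genes, columns=expr.sample_ids))


def invert_combat(
    model: CorrectionModel, expr: ExpressionMatrix, samples: SampleTable
) -> ExpressionMatrix:
    """Exact inverse of :func:`apply_combat` (the correction is affine per
    gene and batch), so apply-then-invert reproduces the input."""
    samples = samples.aligned_to(expr.sample_ids)
    batch = samples.table["batch"].astype(str)
    genes = expr.values.index
    X = expr.values.to_numpy()
    sm_ = _stand_mean_for(model, samples, genes)
    sp = np.sqrt(model.var_pooled.loc[genes].to_numpy())[:, None]
    Z_adj = (X - sm_) / sp
    gam = model.gamma_star.loc[genes, list(batch)].to_numpy()
    del_ = model.delta_star.loc[genes, list(batch)].to_numpy()
    Z = Z_adj * np.sqrt(del_) + gam
    return ExpressionMatrix(pd.DataFrame(Z * sp + sm_, index=genes, columns=expr.sample_ids))
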