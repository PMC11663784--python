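"""Synthetic discovery and validation cohorts.

The generator emulates the study design the pipeline assumes: two discovery
cohorts plus one external validation cohort of pre-treatment rectal-cancer
expression profiles, with

* pCR prevalence per cohort (defaults 26%/19%/21%),
* two opposing planted signal blocks — an "immune" block up-regulated in
  responders and a "stromal/TGFb" block up-regulated in non-responders —
  with within-block correlation from a shared latent factor,
* per-cohort batch location/scale effects (the validation cohort gets
  larger shifts so batch correction is non-trivial), and
* ordinal baseline T/N stage covariates mildly associated with outcome.

Outcome and expression are generated jointly from a Gaussian two-class
factor model: conditional on the latent block factors the class posterior
is exactly logistic (normal discriminant / logistic duality), and each
planted gene's between-class standardized mean difference equals
``effect_size_sd_units`` in expectation, which makes closed-form
parameter-recovery oracles available to the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import ExpressionMatrix, SampleTable

DEFAULT_COHORT_SIZES = {"discovery_a": 125, "discovery_b": 124, "validation": 107}
DEFAULT_PREVALENCE = {"discovery_a": 0.26, "discovery_b": 0.19, "validation": 0.21}

# baseline stage distributions: mostly T3 disease, node involvement common
T_STAGE_PROBS = np.array([0.05, 0.15, 0.60, 0.20])  # T1..T4
N_STAGE_PROBS = np.array([0.35, 0.40, 0.25])  # N0..N2


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    cohort_sizes: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    pcr_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    n_signal_up: int = 40
    n_signal_down: int = 40
    effect_size_sd_units: float = 1.0
    block_correlation: float = 0.3
    batch_location_sd: float = 0.3
    batch_scale_sd: float = 0.1
    validation_batch_multiplier: float = 3.0
    stage_outcome_log_or: float = 0.3
    baseline_mean: float = 7.0
    baseline_mean_sd: float = 1.5
    baseline_sd_log_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_up + self.n_signal_down > self.n_genes:
            raise ConfigError("more planted genes than genes")
        for cohort, p in self.pcr_prevalence.items():
            if not 0 < p < 1:
                raise ConfigError(f"prevalence for {cohort!r} outside (0,1)")
            n = self.cohort_sizes.get(cohort)
            if n is not None and (round(n * p) == 0 or round(n * p) == n):
                raise ConfigError(f"prevalence {p} degenerate at n={n} for {cohort!r}")
        if not 0 <= self.block_correlation < 1:
            raise ConfigError("block_correlation must be in [0,1)")
        if min(self.effect_size_sd_units, self.batch_location_sd, self.batch_scale_sd) < 0:
            raise ConfigError("SD-type parameters must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, sufficient to recompute the
    generating latent scores exactly."""

    cohort: str
    planted_up: list[str]
    planted_down: list[str]
    effect_size_sd_units: float
    gene_means: pd.Series
    gene_sds: pd.Series
    batch_location: pd.Series
    batch_scale: pd.Series
    latent_score: pd.Series  # f_up - f_down per sample; the oracle predictor
    outcome_intercept: float
    stage_outcome_log_or: float
    seed: int


def _shared_gene_params(cfg: SimulationConfig) -> tuple[pd.Index, pd.Series, pd.Series, list, list]:
    """Gene ids, baseline means/SDs and planted-block membership.

    Derived from cfg.seed alone so all cohorts of one study share them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)])
    means = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_mean_sd, cfg.n_genes), index=genes)
    sds = pd.Series(rng.lognormal(0.0, cfg.baseline_sd_log_sigma, cfg.n_genes), index=genes)
    planted_up = list(genes[: cfg.n_signal_up])
    planted_down = list(genes[cfg.n_signal_up : cfg.n_signal_up + cfg.n_signal_down])
    return genes, means, sds, planted_up, planted_down


def _calibrate_intercept(eta_stage: np.ndarray, prevalence: float) -> float:
    """Intercept alpha with mean expit(alpha + eta_stage) == prevalence."""
    f = lambda a: expit(a + eta_stage).mean() - prevalence
    return brentq(f, -30.0, 30.0)


def _cohort_index(cfg: SimulationConfig, cohort_name: str) -> int:
    try:
        return list(cfg.cohort_sizes).index(cohort_name)
    except ValueError:
        raise ConfigError(f"unknown cohort {cohort_name!r}") from None


def simulate_cohort(
    cfg: SimulationConfig, cohort_name: str
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Generate one cohort. Deterministic in (cfg.seed, cohort_name)."""
    idx = _cohort_index(cfg, cohort_name)
    n = cfg.cohort_sizes[cohort_name]
    prevalence = cfg.pcr_prevalence[cohort_name]
    genes, means, sds, planted_up, planted_down = _shared_gene_params(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, idx]))

    t_stage = rng.choice([1, 2, 3, 4], size=n, p=T_STAGE_PROBS)
    n_stage = rng.choice([0, 1, 2], size=n, p=N_STAGE_PROBS)
    # higher stage -> lower pCR odds (centred so calibration is stable)
    eta_stage = -cfg.stage_outcome_log_or * ((t_stage - 3) + (n_stage - 1))
    alpha = _calibrate_intercept(eta_stage, prevalence)
    y = rng.binomial(1, expit(alpha + eta_stage))

    # latent block factors, shifted by class so each planted gene's SMD
    # equals effect_size_sd_units after loading
    rho = cfg.block_correlation
    d = cfg.effect_size_sd_units
    shift = (y - 0.5) * d  # +d/2 responders, -d/2 non-responders
    f_up = rng.normal(0.0, 1.0, n)
    f_down = rng.normal(0.0, 1.0, n)

    z = rng.normal(0.0, 1.0, (cfg.n_genes, n))
    if rho > 0:
        w = np.sqrt(rho)
        r = np.sqrt(1.0 - rho)
        z[: len(planted_up)] = w * f_up + r * z[: len(planted_up)]
        z[len(planted_up) : len(planted_up) + len(planted_down)] = (
            w * f_down + r * z[len(planted_up) : len(planted_up) + len(planted_down)]
        )
    z[: len(planted_up)] += shift
    z[len(planted_up) : len(planted_up) + len(planted_down)] -= shift

    values = means.to_numpy()[:, None] + sds.to_numpy()[:, None] * z

    # per-cohort batch effects on the (gene, cohort) level
    mult = cfg.validation_batch_multiplier if cohort_name == "validation" else 1.0
    batch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 100 + idx]))
    gamma = batch_rng.normal(0.0, mult * cfg.batch_location_sd, cfg.n_genes)
    delta = batch_rng.lognormal(0.0, mult * cfg.batch_scale_sd, cfg.n_genes)
    centred = values - means.to_numpy()[:, None]
    values = means.to_numpy()[:, None] + gamma[:, None] + delta[:, None] * centred

    sample_ids = [f"{cohort_name}_{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": cohort_name,
                "batch": cohort_name,
                "pcr": y,
                "t_stage": t_stage,
                "n_stage": n_stage,
            }
        )
    )
    truth = SyntheticTruth(
        cohort=cohort_name,
        planted_up=planted_up,
        planted_down=planted_down,
        effect_size_sd_units=cfg.effect_size_sd_units,
        gene_means=means,
        gene_sds=sds,
        batch_location=pd.Series(gamma, index=genes),
        batch_scale=pd.Series(delta, index=genes),
        latent_score=pd.Series((f_up + shift) - (f_down - shift), index=sample_ids),
        outcome_intercept=alpha,
        stage_outcome_log_or=cfg.stage_outcome_log_or,
        seed=cfg.seed,
    )
    return expr, samples, truth


def simulate_study(cfg: SimulationConfig) -> dict[str, tuple[ExpressionMatrix, SampleTable, SyntheticTruth]]:
    """Generate every cohort in cfg.cohort_sizes; shared planted truth,
    cohort-specific batch parameters and samples."""
    return {name: simulate_cohort(cfg, name) for name in cfg.cohort_sizes}


def merge_cohorts(
    parts: list[tuple[ExpressionMatrix, SampleTable]]
) -> tuple[ExpressionMatrix, SampleTable]:
    """Column-concatenate cohorts sharing a gene index (discovery merging)."""
    genes = parts[0][0].values.index
    for expr, _ in parts[1:]:
        if not expr.values.index.equals(genes):
            raise ValueError("cohorts do not share a gene index")
    expr = ExpressionMatrix(pd.concat([e.values for e, _ in parts], axis=1))
    samples = SampleTable(pd.concat([s.table for _, s in parts], ignore_index=True))
    return expr, samples
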