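"""Hypothesis-free machine-learning discovery track.

Five stages, mirroring a locked-model development workflow:

1. quality check — drop high-missingness genes, impute the rest by gene
   median, drop outlier samples poorly correlated with the cohort median
   profile;
2. class-imbalance handling — repeated downsampling of the majority
   (non-pCR) class to the minority count, each iteration keeping all
   responders and a fresh seeded draw of non-responders;
3. robust differential expression — per balanced subset, a moderated
   t-test (empirical-Bayes pooled-variance shrinkage) AND a Wilcoxon
   rank-sum test, each Benjamini-Hochberg adjusted; a gene is robust if
   both tests select it in every subset;
4. decision-making-gene (DMG) pruning — recursive importance-based
   elimination, returning the smallest gene set within a tolerance of the
   best cross-validated accuracy;
5. model tournament — six algorithm families x two feature modes (all
   robust DEGs vs the DMG subset) under stratified 10-fold CV accuracy on
   a balanced design; the winner (ties: fewest genes, then fixed
   algorithm order) is refit on all discovery data and frozen into a
   :class:`~radsig.io.LockedModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionMatrix, LockedModel, SampleTable

logger = logging.getLogger("radsig")


class QcError(RuntimeError):
    pass


@dataclass
class QcReport:
    dropped_genes: list[str]
    imputed_cells: int
    dropped_samples: list[str]
    sample_correlations: pd.Series


@dataclass
class DegResult:
    gene: str
    mean_stat_modt: float
    mean_stat_ranksum: float
    median_adj_p_modt: float
    median_adj_p_ranksum: float
    n_iterations_selected: int
    n_iterations: int

    @property
    def robust(self) -> bool:
        return self.n_iterations_selected == self.n_iterations


@dataclass
class CvResult:
    config_id: str
    algorithm_id: str
    feature_mode: str
    fold_accuracies: list[float]
    mean_accuracy: float
    n_genes: int
    failed: bool = False


def quality_check(
    expr_raw: pd.DataFrame,
    samples: SampleTable | None = None,
    max_missing: float = 0.05,
    qc_corr_min: float = 0.7,
) -> tuple[ExpressionMatrix, QcReport]:
    """QC a raw genes x samples frame that may contain missing values."""
    frame = expr_raw.values if isinstance(expr_raw, ExpressionMatrix) else expr_raw
    frame = frame.astype(float)
    miss_frac = frame.isna().mean(axis=1)
    dropped_genes = list(frame.index[miss_frac > max_missing])
    frame = frame.loc[miss_frac <= max_missing]
    n_imputed = int(frame.isna().to_numpy().sum())
    if n_imputed:
        med = frame.median(axis=1)
        frame = frame.T.fillna(med).T
    median_profile = frame.median(axis=1)
    corr = frame.corrwith(median_profile, axis=0)
    dropped_samples = list(corr.index[corr < qc_corr_min])
    if len(dropped_samples) > 0.5 * frame.shape[1]:
        raise QcError(
            f"{len(dropped_samples)}/{frame.shape[1]} samples fail the correlation QC"
        )
    frame = frame.drop(columns=dropped_samples)
    report = QcReport(dropped_genes, n_imputed, dropped_samples, corr)
    if dropped_genes or n_imputed or dropped_samples:
        logger.info(
            "QC: %d genes dropped, %d cells imputed, %d samples dropped",
            len(dropped_genes), n_imputed, len(dropped_samples),
        )
    return ExpressionMatrix(frame), report


def balance_iterations(
    samples: SampleTable, n_iter: int = 100, seed: int = 0
) -> list[list[str]]:
    """Balanced subsets: all minority-class samples plus, per iteration, a
    without-replacement draw of equal size from the majority class."""
    t = samples.table
    y = samples.pcr_vector()
    ids = np.asarray(t["sample_id"])
    pos, neg = ids[y == 1], ids[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    if len(minority) < 2:
        raise ValueError("minority class has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        draw = rng.choice(majority, size=len(minority), replace=False)
        out.append(list(minority) + list(draw))
    return out


# --- moderated t (empirical-Bayes pooled-variance shrinkage) ---------------


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-gene sample variances toward a common prior (scaled
    inverse chi-square fitted by moments on log variances). Returns the
    posterior variances and the prior degrees of freedom d0."""
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = np.nanmean(e)
    evar = np.nanvar(e, ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(evar) or evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        return np.full_like(s2, s0_2), d0
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def moderated_t(X1: np.ndarray, X0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene moderated two-sample t statistic and two-sided p.

    X1, X0: genes x samples arrays for the two classes. Genes with zero
    pooled variance get statistic 0 / p 1.
    """
    n1, n0 = X1.shape[1], X0.shape[1]
    df = n1 + n0 - 2
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    ss = (X1 - m1[:, None]) ** 2
    ss0 = (X0 - m0[:, None]) ** 2
    s2 = (ss.sum(axis=1) + ss0.sum(axis=1)) / df
    post, d0 = _squeeze_var(s2, df)
    denom = np.sqrt(post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m0) / denom, 0.0)
    total_df = df + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), total_df)
    p = np.where(s2 > 0, p, 1.0)
    t = np.where(s2 > 0, t, 0.0)
    return t, p


def _ranksum(X1: np.ndarray, X0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum per gene (z statistic, p)."""
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(X1, X0, axis=1, method="asymptotic", alternative="two-sided")
    n1, n0 = X1.shape[1], X0.shape[1]
    mu = n1 * n0 / 2.0
    # signed standardized U as the reported statistic
    sd = np.sqrt(n1 * n0 * (n1 + n0 + 1) / 12.0)
    z = (res.statistic - mu) / sd
    p = np.asarray(res.pvalue, dtype=float)
    const = (X1.std(axis=1) == 0) & (X0.std(axis=1) == 0) & (X1[:, :1] == X0[:, :1]).ravel()
    p = np.where(const, 1.0, p)
    z = np.where(const, 0.0, z)
    return z, p


def select_degs(
    expr: ExpressionMatrix,
    samples: SampleTable,
    subsets: list[list[str]],
    alpha_adj: float = 0.05,
) -> list[DegResult]:
    """Robust DEG selection over balanced subsets.

    Per subset, a gene is selected iff its BH-adjusted p <= ``alpha_adj``
    for BOTH the moderated t and the rank-sum test; the robust set is the
    intersection across all subsets.
    """
    t = samples.table.set_index("sample_id")
    genes = expr.values.index
    n_sel = np.zeros(len(genes), dtype=int)
    stat_a = np.zeros(len(genes))
    stat_b = np.zeros(len(genes))
    adj_a_all, adj_b_all = [], []
    for subset in subsets:
        y = t.loc[subset, "pcr"].to_numpy(float)
        sub = expr.values[subset].to_numpy()
        X1, X0 = sub[:, y == 1], sub[:, y == 0]
        ta, pa = moderated_t(X1, X0)
        tb, pb = _ranksum(X1, X0)
        adj_a = multipletests(pa, method="fdr_bh")[1]
        adj_b = multipletests(pb, method="fdr_bh")[1]
        n_sel += (adj_a <= alpha_adj) & (adj_b <= alpha_adj)
        stat_a += ta
        stat_b += tb
        adj_a_all.append(adj_a)
        adj_b_all.append(adj_b)
    n_iter = len(subsets)
    med_a = np.median(np.vstack(adj_a_all), axis=0)
    med_b = np.median(np.vstack(adj_b_all), axis=0)
    results = [
        DegResult(
            gene=str(g),
            mean_stat_modt=float(stat_a[i] / n_iter),
            mean_stat_ranksum=float(stat_b[i] / n_iter),
            median_adj_p_modt=float(med_a[i]),
            median_adj_p_ranksum=float(med_b[i]),
            n_iterations_selected=int(n_sel[i]),
            n_iterations=n_iter,
        )
        for i, g in enumerate(genes)
    ]
    logger.info(
        "DEG selection: %d robust genes of %d over %d subsets",
        sum(r.robust for r in results), len(genes), n_iter,
    )
    return results


def robust_genes(results: list[DegResult]) -> list[str]:
    return [r.gene for r in results if r.robust]


# --- DMG pruning ------------------------------------------------------------


def _default_learner(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def select_dmgs(
    expr: ExpressionMatrix,
    samples: SampleTable,
    candidate_genes: list[str],
    learner=None,
    seed: int = 0,
    tol_acc: float = 0.01,
    floor_min: int = 5,
    cv_folds: int = 5,
) -> list[str]:
    """Recursive importance-based elimination over the robust DEG set.

    Repeatedly drops the lowest-importance decile, tracking stratified-CV
    accuracy; returns the smallest set whose accuracy is within
    ``tol_acc`` of the best seen. A learner with neither
    feature_importances_ nor coef_ falls back to ranking by the absolute
    univariable t statistic.
    """
    if not candidate_genes:
        raise ValueError("candidate gene list is empty")
    learner = learner if learner is not None else _default_learner(seed)
    samples = samples.aligned_to(expr.sample_ids)
    y = samples.pcr_vector()
    current = list(candidate_genes)
    path: list[tuple[list[str], float]] = []
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    while True:
        X = expr.values.loc[current].to_numpy().T
        est = clone(learner)
        accs = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        path.append((list(current), float(accs.mean())))
        if len(current) <= floor_min:
            break
        est = clone(learner)
        est.fit(X, y)
        if hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_)
        elif hasattr(est, "coef_"):
            imp = np.abs(np.asarray(est.coef_)).ravel()
        else:
            logger.info("DMG: learner has no importances; ranking by |t| statistic")
            tstat, _ = moderated_t(
                expr.values.loc[current, samples.table.loc[y == 1, "sample_id"]].to_numpy(),
                expr.values.loc[current, samples.table.loc[y == 0, "sample_id"]].to_numpy(),
            )
            imp = np.abs(tstat)
        n_drop = max(1, int(np.ceil(0.1 * len(current))))
        n_keep = max(floor_min, len(current) - n_drop)
        order = np.argsort(-imp, kind="stable")  # descending importance
        current = [current[i] for i in order[:n_keep]]
    best_acc = max(acc for _, acc in path)
    eligible = [(g, acc) for g, acc in path if acc >= best_acc - tol_acc]
    genes, acc = min(eligible, key=lambda t: len(t[0]))
    logger.info("DMG: %d genes at CV accuracy %.3f (best %.3f)", len(genes), acc, best_acc)
    return genes


# --- model tournament -------------------------------------------------------

ALGORITHM_ORDER = ["elastic_net", "gbm", "lasso", "nnet", "rf", "svm"]


def _algorithms(seed: int, grids: dict | None = None):
    """Algorithm family -> (estimator, hyperparameter grid)."""
    grids = grids or {}
    base = {
        "elastic_net": (
            LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=5000, random_state=seed,
            ),
            grids.get("elastic_net", {"clf__C": [0.1, 1.0]}),
        ),
        "gbm": (
            GradientBoostingClassifier(
                n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
            ),
            grids.get("gbm", {}),
        ),
        "lasso": (
            LogisticRegression(l1_ratio=1.0, solver="liblinear", random_state=seed),
            grids.get("lasso", {"clf__C": [0.1, 1.0]}),
        ),
        "nnet": (
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=1000, random_state=seed),
            grids.get("nnet", {}),
        ),
        "rf": (
            RandomForestClassifier(n_estimators=200, random_state=seed),
            grids.get("rf", {}),
        ),
        "svm": (
            SVC(kernel="rbf", probability=True, random_state=seed),
            grids.get("svm", {"clf__C": [1.0]}),
        ),
    }
    return base


def _build_estimator(algo, grid, seed: int):
    pipe = Pipeline([("scale", StandardScaler()), ("clf", algo)])
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_combos > 1:
        return GridSearchCV(pipe, grid, cv=3, scoring="accuracy", n_jobs=1)
    if grid:  # single-combination grid: set directly
        pipe.set_params(**{k: v[0] for k, v in grid.items()})
    return pipe


def train_and_select(
    expr: ExpressionMatrix,
    samples: SampleTable,
    deg_genes: list[str],
    dmg_genes: list[str],
    seed: int = 0,
    cv_folds: int = 10,
    grids: dict | None = None,
) -> tuple[list[CvResult], LockedModel]:
    """Run the 12-configuration tournament and lock the winner.

    Configurations are six algorithm families x two feature modes (all
    robust DEGs, or the DMG subset — the 'functional' mode). CV accuracy
    is computed on a balanced design (all minority samples + one seeded
    majority downsample); the winner is refit on all discovery samples.
    """
    if not deg_genes or not dmg_genes:
        raise ValueError("both gene lists must be non-empty")
    samples = samples.aligned_to(expr.sample_ids)
    balanced_ids = balance_iterations(samples, n_iter=1, seed=seed)[0]
    bal_samples = samples.aligned_to(balanced_ids)
    y_bal = bal_samples.pcr_vector()
    modes = {"deg": list(deg_genes), "dmg": list(dmg_genes)}
    min_class = int(min((y_bal == 1).sum(), (y_bal == 0).sum()))
    if min_class < cv_folds:
        logger.warning("reducing CV folds from %d to %d (small class)", cv_folds, min_class)
        cv_folds = min_class
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    results: list[CvResult] = []
    for algo_id in ALGORITHM_ORDER:
        algo, grid = _algorithms(seed, grids)[algo_id]
        for mode, genes in modes.items():
            cid = f"{algo_id}:{mode}"
            X = expr.values.loc[genes, balanced_ids].to_numpy().T
            est = _build_estimator(algo, grid, seed)
            try:
                accs = cross_val_score(est, X, y_bal, cv=cv, scoring="accuracy", error_score="raise")
            except Exception as exc:
                logger.warning("configuration %s failed: %s", cid, exc)
                results.append(CvResult(cid, algo_id, mode, [], float("nan"), len(genes), failed=True))
                continue
            results.append(
                CvResult(cid, algo_id, mode, [float(a) for a in accs], float(accs.mean()), len(genes))
            )
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError("every model configuration failed")
    # highest accuracy; ties -> fewest genes -> fixed algorithm order
    order = {a: i for i, a in enumerate(ALGORITHM_ORDER)}
    winner = min(ok, key=lambda r: (-r.mean_accuracy, r.n_genes, order[r.algorithm_id]))
    algo, grid = _algorithms(seed, grids)[winner.algorithm_id]
    genes = modes[winner.feature_mode]
    est = _build_estimator(algo, grid, seed)
    X_full = expr.values.loc[genes].to_numpy().T
    y_full = samples.pcr_vector()
    est.fit(X_full, y_full)
    fitted = est.best_estimator_ if isinstance(est, GridSearchCV) else est
    hyper = (
        {k: v for k, v in est.best_params_.items()} if isinstance(est, GridSearchCV)
        else {k: v[0] for k, v in grid.items()}
    )
    model = LockedModel(
        algorithm_id=winner.algorithm_id,
        gene_list=genes,
        hyperparameters=hyper,
        estimator=fitted,
        training_seed=seed,
        cv_accuracy=winner.mean_accuracy,
        created_from=f"tournament:{winner.config_id}",
    )
    logger.info(
        "tournament winner %s: CV accuracy %.3f with %d genes",
        winner.config_id, winner.mean_accuracy, winner.n_genes,
    )
    return results, model
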