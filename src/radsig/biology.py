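"""Biological characterization of a locked predictor.

Ranks genes by a signed standardized mean difference between two sample
classes (e.g. predicted-responder vs predicted-non-responder), runs
preranked gene-set enrichment with the weighted Kolmogorov-Smirnov running
sum and a gene-permutation null, compares two enrichment analyses for
shared, sign-concordant hallmark sets, meta-analyses per-gene regressions
against biology feature scores across cohorts, and assigns model genes to
sorted-cell-population types by fold-change specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .candidates import MetaResult, meta_analyse
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("radsig")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    direction: str  # up_in_class1 | up_in_class0
    leading_edge: list[str]
    set_size: int


@dataclass
class CellTypeAssignment:
    gene: str
    assigned: str  # epithelial | leucocyte | endothelial | fibroblast | none
    fold_change: float


def rank_genes(expr: ExpressionMatrix, class_labels) -> pd.Series:
    """Signed standardized mean difference (class1 - class0) per gene,
    sorted descending; ties broken by gene id."""
    y = np.asarray(class_labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = expr.values.to_numpy()
    X1, X0 = X[:, y == 1], X[:, y == 0]
    n1, n0 = X1.shape[1], X0.shape[1]
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    sp2 = ((n1 - 1) * X1.var(axis=1, ddof=1) + (n0 - 1) * X0.var(axis=1, ddof=1)) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        smd = np.where(sp2 > 0, (m1 - m0) / np.sqrt(sp2), 0.0)
    s = pd.Series(smd, index=expr.values.index, name="smd")
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], str(s.index[i])))
    return s.iloc[order]


def _running_es(metric: np.ndarray, in_set: np.ndarray, weight_p: float) -> tuple[float, int]:
    """ES (signed extreme of the running sum) and its position."""
    n = len(metric)
    nh = int(in_set.sum())
    w = np.abs(metric) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero metrics in the set: fall back to unweighted
        hit_w = in_set.astype(float)
        total = float(nh)
    steps = hit_w / total - (~in_set) / float(n - nh)
    run = np.cumsum(steps)
    imax, imin = int(np.argmax(run)), int(np.argmin(run))
    if run[imax] >= -run[imin]:
        return float(run[imax]), imax
    return float(run[imin]), imin


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> list[EnrichmentResult]:
    """Preranked GSEA with the weighted KS running sum.

    ``ranking`` is a descending (gene -> metric) series. The null permutes
    gene labels: each permutation re-draws the set's positions in the
    ranking. NES = ES / mean |null ES| of matching sign; nominal p from
    the same-sign null tail; BH FDR across the tested sets.
    """
    metric = ranking.to_numpy(float)
    genes = list(ranking.index)
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)
    results = []
    for name, members in sets.items():
        hit_idx = [pos[g] for g in members if g in pos]
        if len(hit_idx) < min_size:
            logger.warning("set %r skipped: %d genes in ranking < %d", name, len(hit_idx), min_size)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[hit_idx] = True
        es, es_pos = _running_es(metric, in_set, weight_p)
        null = np.empty(n_perm)
        k = len(hit_idx)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _running_es(metric, perm, weight_p)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same):
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
            nes = es / np.mean(np.abs(same))
        else:
            p, nes = 1.0 / (n_perm + 1), 0.0
        sorted_hits = sorted(hit_idx)
        if es >= 0:
            le = [genes[i] for i in sorted_hits if i <= es_pos]
        else:
            le = [genes[i] for i in sorted_hits if i >= es_pos]
        results.append(
            EnrichmentResult(
                set_name=name, es=es, nes=float(nes), p_value=float(p), fdr=float("nan"),
                direction="up_in_class1" if es >= 0 else "up_in_class0",
                leading_edge=le, set_size=len(hit_idx),
            )
        )
    if results:
        fdrs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


def concordance_of_contrasts(
    enrich_a: list[EnrichmentResult],
    enrich_b: list[EnrichmentResult],
    fdr_cut: float = 0.25,
) -> dict:
    """Shared vs analysis-specific significant sets, with direction
    agreement among the shared ones."""
    sig_a = {r.set_name: r for r in enrich_a if r.fdr <= fdr_cut}
    sig_b = {r.set_name: r for r in enrich_b if r.fdr <= fdr_cut}
    shared = sorted(set(sig_a) & set(sig_b))
    agree = [s for s in shared if sig_a[s].direction == sig_b[s].direction]
    return {
        "shared": shared,
        "a_only": sorted(set(sig_a) - set(sig_b)),
        "b_only": sorted(set(sig_b) - set(sig_a)),
        "n_shared": len(shared),
        "n_sign_agree": len(agree),
        "sign_agreement": len(agree) / len(shared) if shared else float("nan"),
    }


def gene_feature_meta(
    exprs: dict[str, ExpressionMatrix],
    feature_scores: dict[str, pd.DataFrame],
    genes: list[str],
) -> dict[tuple[str, str], MetaResult]:
    """Per (gene, feature): linear regression of gene expression on the
    feature score within each cohort, pooled by fixed-effect inverse
    variance with heterogeneity. Cohorts where a feature is constant are
    excluded for that feature (warned)."""
    out: dict[tuple[str, str], MetaResult] = {}
    features = sorted({c for f in feature_scores.values() for c in f.columns})
    for feat in features:
        cohort_data = []
        for cohort, expr in exprs.items():
            score = feature_scores[cohort][feat]
            score = score.reindex(expr.sample_ids)
            if score.std(ddof=0) == 0 or score.isna().any():
                logger.warning("feature %r constant/missing in cohort %r; excluded", feat, cohort)
                continue
            cohort_data.append((expr, score))
        if not cohort_data:
            continue
        for gene in genes:
            betas, ses = [], []
            for expr, score in cohort_data:
                if gene not in expr.values.index:
                    continue
                x = score.to_numpy(float)
                yv = expr.values.loc[gene].to_numpy(float)
                xc = x - x.mean()
                sxx = (xc**2).sum()
                beta = float((xc * yv).sum() / sxx)
                resid = yv - yv.mean() - beta * xc
                dof = len(yv) - 2
                se = float(np.sqrt((resid**2).sum() / dof / sxx))
                betas.append(beta)
                ses.append(se)
            if betas:
                out[(gene, feat)] = meta_analyse(betas, ses, feature=f"{gene}~{feat}")
    return out


def assign_cell_types(
    reference: pd.DataFrame,
    genes: list[str],
    fc_threshold: float = 2.0,
) -> list[CellTypeAssignment]:
    """Assign each gene to its top-expressing sorted-population type iff
    the linear-scale fold-change over the next-highest type reaches the
    threshold (>= rule); otherwise 'none'. Reference: genes x cell types,
    linear scale."""
    out = []
    for gene in genes:
        if gene not in reference.index:
            logger.warning("gene %r absent from cell-type reference", gene)
            out.append(CellTypeAssignment(gene, "none", float("nan")))
            continue
        vals = reference.loc[gene].astype(float).sort_values(ascending=False)
        top, second = vals.iloc[0], vals.iloc[1]
        fc = float(top / second) if second > 0 else float("inf")
        if fc >= fc_threshold:
            out.append(CellTypeAssignment(gene, str(vals.index[0]), fc))
        else:
            out.append(CellTypeAssignment(gene, "none", fc))
    return out
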