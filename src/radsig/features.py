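"""Per-sample candidate features from expression and ancillary tables.

Covers the hypothesis-based candidates: signature scores (mean of per-gene
z-scores, or a weighted sum for published coefficient signatures such as
RSI), marker-mean cell-population abundance scores (MCP-counter
convention), nearest-centroid molecular subtype calls (CMS-style), the
chromosomal-instability flag from copy-number segments, and mutation
burden counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SegmentTable,
    SignatureDef,
    ValidationError,
)

logger = logging.getLogger("radsig")


class ScoringError(ValueError):
    pass


class ClassificationError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Samples x features score matrix with per-feature kind
    (continuous / binary / categorical)."""

    scores: pd.DataFrame  # index = sample ids, columns = feature names
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        for col in self.scores.columns:
            kind = self.kinds.get(col, "continuous")
            vals = self.scores[col].dropna()
            if kind == "continuous" and len(vals) and not np.isfinite(vals.to_numpy(float)).all():
                raise ValidationError(f"non-finite continuous scores in {col!r}")
            if kind == "binary" and len(vals) and not set(vals.astype(float)) <= {0.0, 1.0}:
                raise ValidationError(f"non-binary values in {col!r}")

    def add(self, name: str, values: pd.Series, kind: str = "continuous") -> None:
        self.scores[name] = values
        self.kinds[name] = kind
        ScoreTable.__post_init__(self)

    @staticmethod
    def empty(sample_ids) -> "ScoreTable":
        return ScoreTable(pd.DataFrame(index=pd.Index(sample_ids, name="sample_id")), {})


@dataclass
class CentroidModel:
    """Per-class centroid vectors over one shared gene list, plus the
    correlation threshold below which a sample is 'unclassified'."""

    centroids: pd.DataFrame  # genes x classes
    threshold: float = 0.15
    min_gene_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValidationError("centroid threshold must be in [-1,1]")


def _present_genes(expr: ExpressionMatrix, genes, context: str) -> list[str]:
    present = [g for g in genes if g in expr.values.index]
    if not present:
        raise ScoringError(f"{context}: no gene present in expression matrix")
    return present


def score_signature(
    expr: ExpressionMatrix, sig: SignatureDef, method: str = "mean_z"
) -> pd.Series:
    """Score one signature per sample.

    ``mean_z``: mean over present genes of per-gene z-scores, z computed
    across the scored cohort. ``weighted_sum``: sum of weight_g * expr_g.
    ``sig.direction == -1`` negates the score.
    """
    present = _present_genes(expr, sig.genes, f"signature {sig.name!r}")
    sub = expr.values.loc[present]
    if method == "mean_z":
        sd = sub.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "signature %r: %d zero-variance genes excluded", sig.name, int((~keep).sum())
            )
        if not keep.any():
            raise ScoringError(f"signature {sig.name!r}: all present genes zero-variance")
        sub = sub[keep]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        score = z.mean(axis=0)
    elif method == "weighted_sum":
        weights = sig.weights if sig.weights is not None else np.ones(len(sig.genes))
        wmap = dict(zip(sig.genes, weights))
        w = np.array([wmap[g] for g in present])
        score = pd.Series(w @ sub.to_numpy(), index=sub.columns)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return (sig.direction * score).rename(sig.name)


def score_cell_populations(
    expr: ExpressionMatrix, marker_sets: GeneSetCollection
) -> ScoreTable:
    """Marker-mean abundance scores: per population, the arithmetic mean of
    member-gene log2 expression; no cross-sample normalization."""
    out = ScoreTable.empty(expr.sample_ids)
    for name, members in marker_sets.items():
        present = [g for g in members if g in expr.values.index]
        if not present:
            logger.warning("cell population %r: no marker present; column set missing", name)
            out.scores[name] = np.nan
            out.kinds[name] = "continuous"
            continue
        out.add(name, expr.values.loc[present].mean(axis=0))
    return out


def classify_subtype(
    expr: ExpressionMatrix, model: CentroidModel
) -> pd.DataFrame:
    """Nearest-centroid subtype call per sample.

    Returns a frame (sample_id index) with columns ``call`` and
    ``correlation``; max Pearson correlation below the threshold yields
    'unclassified'. Ties break on centroid column order (logged).
    """
    shared = [g for g in model.centroids.index if g in expr.values.index]
    frac = len(shared) / len(model.centroids.index)
    if frac < model.min_gene_fraction:
        raise ClassificationError(
            f"only {frac:.0%} of centroid genes present (< {model.min_gene_fraction:.0%})"
        )
    X = expr.values.loc[shared].to_numpy()  # genes x samples
    C = model.centroids.loc[shared].to_numpy()  # genes x classes
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(Cc, axis=0)
    xn[xn == 0] = np.nan
    with np.errstate(invalid="ignore"):
        corr = (Xc.T @ Cc) / np.outer(xn, cn)  # samples x classes
    best = np.nanargmax(corr, axis=1)
    best_r = corr[np.arange(corr.shape[0]), best]
    ties = (corr == best_r[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("subtype ties for %d samples; broken by class order", int(ties.sum()))
    classes = list(model.centroids.columns)
    calls = [classes[b] if r >= model.threshold else "unclassified" for b, r in zip(best, best_r)]
    return pd.DataFrame(
        {"call": calls, "correlation": best_r},
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )


def classify_cin(segments: SegmentTable, neutral_fraction_max: float = 0.20) -> pd.Series:
    """Binary chromosomal-instability flag per sample.

    Samples whose neutral copy-number calls cover more than
    ``neutral_fraction_max`` (default 20%) of the combined length of all
    segments are CIN-negative (0); otherwise CIN-positive (1). Segment
    lengths are 1-based inclusive (end - start + 1).
    """
    t = segments.table
    lengths = (t["end"] - t["start"] + 1).astype(float)
    total = lengths.groupby(t["sample_id"]).sum()
    neutral = lengths.where(t["call"] == "neutral", 0.0).groupby(t["sample_id"]).sum()
    frac = neutral / total
    return (~(frac > neutral_fraction_max)).astype(int).rename("cin")


def mutation_burden(
    mutations: pd.DataFrame,
    sample_ids,
    classes: set | None = frozenset({"missense", "nonsense", "frameshift", "splice"}),
) -> pd.Series:
    """Count of (by default nonsynonymous) mutation records per sample.

    ``classes=None`` counts every record. Samples absent from the table
    get 0 (logged).
    """
    counts = pd.Series(0, index=pd.Index(sample_ids, name="sample_id"), dtype=int)
    if len(mutations):
        t = mutations
        if classes is not None and "class" in t.columns:
            t = t[t["class"].isin(classes)]
        got = t.groupby("sample_id").size()
        got = got[got.index.isin(counts.index)]
        counts.loc[got.index] = got.astype(int)
    absent = set(sample_ids) - set(mutations["sample_id"]) if len(mutations) else set(sample_ids)
    if absent:
        logger.warning("mutation burden: %d samples absent from table, counted 0", len(absent))
    return counts.rename("mutation_burden")
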