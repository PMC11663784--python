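"""Core domain types and on-disk formats.

Every stage of the pipeline exchanges a small set of objects: a log2
expression matrix (genes x samples), a per-sample annotation table with
outcome and covariates, gene-set collections (GMT), weighted signature
definitions, copy-number segment tables, and a locked (frozen) predictive
model. This module owns those types, their invariants, and their
readers/writers. All matrices are oriented genes-in-rows; a single
canonical orientation avoids silent transposition bugs.
"""

from __future__ import annotations

import base64
import hashlib
import io as _io
import json
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("radsig")

MODEL_SCHEMA_VERSION = 1

MANDATORY_SAMPLE_COLUMNS = ("sample_id", "cohort", "batch", "pcr", "t_stage", "n_stage")


class FormatError(ValueError):
    """Malformed on-disk input (bad header, wrong field count...)."""


class ParseError(ValueError):
    """Unparseable cell value, with its location."""


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicate ids, missing values...)."""


class IntegrityError(ValueError):
    """Serialized model payload does not match its recorded hash."""


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, no missing values.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    Construction validates uniqueness and finiteness; use
    :meth:`from_frame` for inputs that may still need collapsing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate gene ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains missing or non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)])

    @staticmethod
    def from_frame(frame: pd.DataFrame, collapse: str = "max_mean") -> "ExpressionMatrix":
        """Build a matrix, collapsing duplicate gene rows.

        ``collapse='max_mean'`` keeps, per gene id, the row with the highest
        mean expression — the standard deterministic probeset-to-gene rule.
        """
        if frame.index.has_duplicates:
            if collapse != "max_mean":
                raise ValueError(f"unknown collapse rule: {collapse!r}")
            means = frame.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            frame = frame.iloc[order]
            frame = frame[~frame.index.duplicated(keep="first")]
            frame = frame.sort_index()
            logger.info("collapsed duplicate gene rows by max-mean; %d genes retained", len(frame))
        return ExpressionMatrix(frame)


def _check_log2_scale(values: pd.DataFrame, assume_log2: bool) -> None:
    if assume_log2 and values.size and values.to_numpy().max() > 30:
        logger.warning(
            "max expression value %.1f > 30: input may not be log2-scaled "
            "(no transformation applied)",
            values.to_numpy().max(),
        )


def read_expression(
    path,
    format: str = "tsv",
    collapse: str = "max_mean",
    assume_log2: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV (genes in rows, sample-id header)
    or MatrixMarket (``<path>`` plus ``<path>.genes.txt`` / ``<path>.samples.txt``).
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        sample_header = header[1:]
        if len(set(sample_header)) != len(sample_header):
            raise ValidationError(f"{path}: duplicate sample id in header")
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # header/IO level problems
            raise FormatError(f"cannot read expression TSV {path}: {exc}") from exc
        if frame.columns.size == 0:
            raise FormatError(f"{path}: no sample columns in header")
        non_numeric = frame.columns[[not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]]
        if len(non_numeric):
            col = non_numeric[0]
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
    elif format == "mtx":
        genes = [ln.strip() for ln in open(f"{path}.genes.txt") if ln.strip()]
        samples = [ln.strip() for ln in open(f"{path}.samples.txt") if ln.strip()]
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        frame = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if pd.Index(frame.columns).has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids in header")
    _check_log2_scale(frame, assume_log2)
    return ExpressionMatrix.from_frame(frame.astype(float), collapse=collapse)


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values.to_numpy()))
        with open(f"{path}.genes.txt", "w") as fh:
            fh.write("\n".join(expr.gene_ids) + "\n")
        with open(f"{path}.samples.txt", "w") as fh:
            fh.write("\n".join(expr.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Sample annotation


@dataclass
class SampleTable:
    """Per-sample outcome (pCR in {0,1} or NA), cohort/batch labels, and
    ordinal baseline stage covariates (t_stage 1-4, n_stage 0-2)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_SAMPLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in annotation table")
        pcr = self.table["pcr"].dropna()
        if len(pcr) and not set(pcr.astype(int)) <= {0, 1}:
            raise ValidationError("pcr must be 0/1 or missing")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned_to(self, sample_ids) -> "SampleTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)

    def pcr_vector(self, require: bool = True) -> np.ndarray:
        pcr = self.table["pcr"]
        if require and pcr.isna().any():
            raise ValidationError("pcr missing for samples used in modelling")
        return pcr.to_numpy(dtype=float)


def read_samples(path) -> SampleTable:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str, "batch": str})
    return SampleTable(table)


def write_samples(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signatures and gene sets


@dataclass
class SignatureDef:
    """A scored gene signature: members, optional per-gene weights, and an
    overall direction (-1 flips the score sign)."""

    name: str
    genes: list[str]
    weights: np.ndarray | None = None
    direction: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r}: duplicate genes")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.genes),):
                raise ValidationError(f"signature {self.name!r}: weights misaligned with genes")
        if self.direction not in (1, -1):
            raise ValidationError(f"signature {self.name!r}: direction must be +1 or -1")


class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        self.sets = {}
        self.descriptions = descriptions or {}
        for name, members in sets.items():
            if name in self.sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    logger.warning("gene set %r lists member %r twice; deduplicated", name, m)
                seen[m] = None
            self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}:{i}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_signatures(path) -> list[SignatureDef]:
    """Read weighted signature definitions from a long-format TSV with
    columns name, gene, weight (optional), direction (optional)."""
    table = pd.read_csv(path, sep="\t")
    if "name" not in table.columns or "gene" not in table.columns:
        raise FormatError(f"{path}: signature TSV needs 'name' and 'gene' columns")
    out = []
    for name, grp in table.groupby("name", sort=False):
        weights = grp["weight"].to_numpy(float) if "weight" in grp.columns else None
        direction = int(grp["direction"].iloc[0]) if "direction" in grp.columns else 1
        out.append(SignatureDef(str(name), [str(g) for g in grp["gene"]], weights, direction))
    return out


# ---------------------------------------------------------------------------
# Copy-number segments


@dataclass
class SegmentTable:
    """Copy-number segments: (sample_id, chrom, start, end, call) with
    1-based inclusive coordinates and call in {loss, neutral, gain}."""

    table: pd.DataFrame

    VALID_CALLS = frozenset({"loss", "neutral", "gain"})

    def __post_init__(self) -> None:
        need = {"sample_id", "chrom", "start", "end", "call"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValidationError(f"segment table missing columns: {sorted(missing)}")
        bad_call = set(self.table["call"]) - self.VALID_CALLS
        if bad_call:
            raise ValidationError(f"unknown copy-number calls: {sorted(bad_call)}")
        if (self.table["end"] < self.table["start"]).any():
            raise ValidationError("segment with end < start")
        for (sid, chrom), grp in self.table.groupby(["sample_id", "chrom"]):
            grp = grp.sort_values("start")
            if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping segments for sample {sid!r} chrom {chrom!r}")


def read_segments(path) -> SegmentTable:
    return SegmentTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str}))


def write_segments(segments: SegmentTable, path) -> None:
    segments.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Locked model


@dataclass
class LockedModel:
    """A frozen predictor: algorithm id, gene list, hyperparameters, the
    fitted estimator, and the training seed.

    Validation applies a locked model but never refits it; :meth:`hash`
    fingerprints the fitted payload so any mutation is detectable.
    """

    algorithm_id: str
    gene_list: list[str]
    hyperparameters: dict
    estimator: object
    training_seed: int
    cv_accuracy: float = float("nan")
    created_from: str = ""

    def __post_init__(self) -> None:
        if not self.gene_list:
            raise ValidationError("locked model: empty gene list")
        if len(set(self.gene_list)) != len(self.gene_list):
            raise ValidationError("locked model: duplicate genes")

    def _payload(self) -> bytes:
        return pickle.dumps(self.estimator, protocol=4)

    def hash(self) -> str:
        return hashlib.sha256(self._payload()).hexdigest()

    def predict_scores(self, expr: ExpressionMatrix) -> np.ndarray:
        """Continuous response score (probability of pCR where the
        estimator supports it) for each sample in ``expr``."""
        missing = [g for g in self.gene_list if g not in expr.values.index]
        if missing:
            raise ValidationError(f"model genes absent from matrix: {missing[:10]}")
        X = expr.values.loc[self.gene_list].to_numpy().T
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float)
        return np.asarray(est.predict(X), dtype=float)


def save_model(model: LockedModel, path) -> None:
    payload = model._payload()
    envelope = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "algorithm_id": model.algorithm_id,
        "gene_list": model.gene_list,
        "hyperparameters": model.hyperparameters,
        "seed": model.training_seed,
        "cv_accuracy": model.cv_accuracy,
        "created_from": model.created_from,
        "payload_base64": base64.b64encode(payload).decode("ascii"),
        "payload_sha256": hashlib.sha256(payload).hexdigest(),
    }
    with open(path, "w") as fh:
        json.dump(envelope, fh, indent=1)


def load_model(path) -> LockedModel:
    with open(path) as fh:
        envelope = json.load(fh)
    if "schema_version" not in envelope:
        raise FormatError(f"{path}: no schema_version field (unsupported legacy model file)")
    if envelope["schema_version"] != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema version {envelope['schema_version']}"
        )
    payload = base64.b64decode(envelope["payload_base64"])
    digest = hashlib.sha256(payload).hexdigest()
    if digest != envelope["payload_sha256"]:
        raise IntegrityError(f"{path}: payload hash mismatch")
    estimator = pickle.loads(payload)
    return LockedModel(
        algorithm_id=envelope["algorithm_id"],
        gene_list=list(envelope["gene_list"]),
        hyperparameters=dict(envelope["hyperparameters"]),
        estimator=estimator,
        training_seed=int(envelope["seed"]),
        cv_accuracy=float(envelope.get("cv_accuracy", float("nan"))),
        created_from=envelope.get("created_from", ""),
    )
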