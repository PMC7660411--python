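"""Gene expression matrix (GEM) I/O and normalization.

A GEM is a plain tab-delimited table of FPKM-like non-negative expression
values, conventionally stored genes-as-rows with a header row of sample ids
and a first column of gene ids. In memory the matrix is always oriented
samples x genes. The normalization chain applied before any modeling is

    log2(v + 1)  ->  quantile normalization across samples
                 ->  optional gene-set subsetting (GMT)
                 ->  per-gene min-max scaling to [0, 1]

and the container tracks which state it is in so downstream stages can
enforce their preconditions.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationState",
    "ExpressionMatrix",
    "GeneSet",
    "MinMaxScaler",
    "read_gem",
    "write_gem",
    "read_labels",
    "write_labels",
    "read_gmt",
    "log2_transform",
    "quantile_normalize",
    "subset_genes",
    "minmax_fit_transform",
]


class NormalizationState(str, enum.Enum):
    RAW = "raw"
    LOG2 = "log2"
    QUANTILE = "quantile"
    MINMAX = "minmax"


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with ids, labels and a state tag.

    Invariants (checked on construction): shape matches the id lists, ids
    are unique, no NaN/inf entries, raw/log2 values are non-negative and
    minmax values lie in [0, 1].
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str] | None = None
    normalization_state: NormalizationState = NormalizationState.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains NaN/inf entries")
        state = NormalizationState(self.normalization_state)
        self.normalization_state = state
        if state in (NormalizationState.RAW, NormalizationState.LOG2):
            if (self.values < 0).any():
                raise ValueError(f"negative values not allowed in {state.value} state")
        elif state is NormalizationState.MINMAX:
            if (self.values < 0).any() or (self.values > 1).any():
                raise ValueError("minmax-state values must lie in [0, 1]")
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise ValueError(f"samples without labels: {missing[:5]}")
            self.labels = {s: str(self.labels[s]) for s in self.sample_ids}

    # -- convenience accessors ------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("matrix has no labels attached")
        return np.array([self.labels[s] for s in self.sample_ids])

    def classes(self) -> list[str]:
        return sorted(set(self.label_array().tolist()))

    def with_labels(self, labels: dict[str, str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy(), labels=dict(labels))

    def select_samples(self, mask_or_ids) -> "ExpressionMatrix":
        """Subset to the given boolean mask or explicit sample-id list."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in mask_or_ids], dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        labels = None if self.labels is None else {s: self.labels[s] for s in ids}
        return ExpressionMatrix(self.values[idx], list(self.gene_ids), ids,
                                labels, self.normalization_state)

    def to_frame(self) -> pd.DataFrame:
        """Genes-as-rows DataFrame (the on-disk convention)."""
        return pd.DataFrame(self.values.T, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class GeneSet:
    """A named, ordered, duplicate-free collection of gene identifiers."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene in set {self.name!r}")


@dataclass
class MinMaxScaler:
    """Per-gene affine map onto [0, 1], with inverse.

    Constant genes (max == min) are mapped to 0 rather than dropped so gene
    indexing stays aligned with gene sets; their inverse maps back to the
    fitted minimum.
    """

    per_gene_min: np.ndarray
    per_gene_max: np.ndarray

    def __post_init__(self) -> None:
        self.per_gene_min = np.asarray(self.per_gene_min, dtype=float)
        self.per_gene_max = np.asarray(self.per_gene_max, dtype=float)
        if self.per_gene_min.shape != self.per_gene_max.shape:
            raise ValueError("min/max vectors must have equal length")
        if (self.per_gene_max < self.per_gene_min).any():
            raise ValueError("per_gene_max must be >= per_gene_min")

    @property
    def _span(self) -> np.ndarray:
        return self.per_gene_max - self.per_gene_min

    def transform(self, values: np.ndarray) -> np.ndarray:
        span = self._span
        safe = np.where(span > 0, span, 1.0)
        out = (values - self.per_gene_min) / safe
        out[:, span == 0] = 0.0
        return out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return values * self._span + self.per_gene_min


def _check_unique(items: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    if dups:
        raise ValueError(f"duplicate {what}(s): {dups}")


# -- file readers / writers ---------------------------------------------


def read_gem(path, orientation: str = "genes_as_rows") -> ExpressionMatrix:
    """Read a tab-delimited GEM with one header row of ids and one id column.

    ``orientation`` states how the FILE is laid out; the returned matrix is
    always samples x genes. Duplicate ids, ragged rows and non-numeric
    cells raise with the offending coordinates.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    n_cols = len(header)
    row_ids: list[str] = []
    data = np.empty((len(rows) - 1, n_cols - 1))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: ragged row at line {r}: expected {n_cols} fields, "
                f"got {len(row)}")
        row_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:], start=2):
            try:
                data[r - 2, c - 2] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at line {r}, column {c}: "
                    f"{cell!r}") from None
    if orientation == "genes_as_rows":
        gene_ids, sample_ids, values = row_ids, col_ids, data.T
    else:
        gene_ids, sample_ids, values = col_ids, row_ids, data
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_gem(E: ExpressionMatrix, path, orientation: str = "genes_as_rows") -> None:
    """Write a GEM as tab-delimited text at full float precision."""
    if orientation == "genes_as_rows":
        row_ids, col_ids, values = E.gene_ids, E.sample_ids, E.values.T
    elif orientation == "samples_as_rows":
        row_ids, col_ids, values = E.sample_ids, E.gene_ids, E.values
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([""] + list(col_ids))
        for rid, row in zip(row_ids, values):
            w.writerow([rid] + [repr(float(v)) for v in row])


_LABEL_HEADER_FIRST = {"sample", "sample_id", "sampleid", "id", "name"}
_LABEL_HEADER_SECOND = {"label", "class", "group", "condition"}


def read_labels(path) -> dict[str, str]:
    """Read a two-column (sample id, label) TSV; header auto-detected.

    A sample listed twice with the same label is tolerated; conflicting
    labels raise.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and any(f.strip() for f in r)]
    if not rows:
        return {}
    first = rows[0]
    if (len(first) >= 2 and first[0].strip().lower() in _LABEL_HEADER_FIRST
            and first[1].strip().lower() in _LABEL_HEADER_SECOND):
        rows = rows[1:]
    out: dict[str, str] = {}
    for i, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise ValueError(f"{path}: line {i}: expected 2 tab-separated fields")
        sid, label = row[0].strip(), row[1].strip()
        if sid in out and out[sid] != label:
            raise ValueError(
                f"{path}: sample {sid!r} listed with conflicting labels "
                f"{out[sid]!r} and {label!r}")
        out[sid] = label
    return out


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, label in labels.items():
            w.writerow([sid, label])


def read_gmt(path) -> list[GeneSet]:
    """Read GMT gene sets (name, description, genes...; tab-delimited).

    The description column is discarded; duplicate genes within a line are
    dropped (order preserved) with a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not any(f.strip() for f in row):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{path}: line {i}: GMT lines need name, description and "
                    f"at least one gene (got {len(row)} fields)")
            name = row[0].strip()
            genes: list[str] = []
            seen: set[str] = set()
            n_dup = 0
            for g in (f.strip() for f in row[2:]):
                if not g:
                    continue
                if g in seen:
                    n_dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if n_dup:
                logger.warning("gene set %s: dropped %d duplicate gene id(s)",
                               name, n_dup)
            sets.append(GeneSet(name, genes))
    return sets


# -- normalization chain ------------------------------------------------


def log2_transform(E: ExpressionMatrix) -> ExpressionMatrix:
    """log2(v + 1) on a raw-state matrix (pseudocount handles FPKM zeros)."""
    if E.normalization_state is not NormalizationState.RAW:
        raise ValueError(f"log2_transform expects raw state, got {E.normalization_state.value}")
    if (E.values < 0).any():
        raise ValueError("negative expression values cannot be log-transformed")
    return replace(E, values=np.log2(E.values + 1.0),
                   normalization_state=NormalizationState.LOG2)


def quantile_normalize(E: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common across-sample quantile profile.

    Each sample's r-th smallest value is replaced by the mean, over all
    samples, of their r-th smallest values. Tied values within a sample
    receive the mean of the reference values at the ranks they jointly
    occupy, so equal inputs stay equal.
    """
    if E.normalization_state is not NormalizationState.LOG2:
        raise ValueError(f"quantile_normalize expects log2 state, got {E.normalization_state.value}")
    out_state = NormalizationState.QUANTILE
    if E.n_genes < 2 or E.n_samples < 2:
        return replace(E, values=E.values.copy(), normalization_state=out_state)
    values = E.values
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        row = values[i]
        order = np.argsort(row, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average the reference within groups of tied input values
        out[i] = pd.Series(ranked).groupby(row, sort=False).transform("mean").to_numpy()
    return replace(E, values=out, normalization_state=out_state)


def subset_genes(E: ExpressionMatrix, S: GeneSet) -> ExpressionMatrix:
    """Restrict the matrix to the genes of ``S`` (in the set's order).

    Genes of ``S`` absent from the matrix are dropped with a warning; an
    empty intersection raises.
    """
    pos = {g: i for i, g in enumerate(E.gene_ids)}
    kept = [g for g in S.genes if g in pos]
    missing = len(S.genes) - len(kept)
    if not kept:
        raise ValueError(
            f"gene set {S.name!r} shares no genes with the matrix "
            f"({len(S.genes)} requested)")
    if missing:
        logger.warning("gene set %s: %d of %d genes absent from matrix, dropped",
                       S.name, missing, len(S.genes))
    idx = np.array([pos[g] for g in kept], dtype=int)
    return replace(E, values=E.values[:, idx], gene_ids=kept)


def minmax_fit_transform(E: ExpressionMatrix) -> tuple[ExpressionMatrix, MinMaxScaler]:
    """Scale each gene to [0, 1] over the samples of ``E``.

    Returns the scaled matrix and the fitted scaler, retained so held-out
    or patient samples can be projected onto the same scale and so the
    mapping can be inverted.
    """
    if E.normalization_state not in (NormalizationState.LOG2, NormalizationState.QUANTILE):
        raise ValueError(
            f"minmax_fit_transform expects log2 or quantile state, got "
            f"{E.normalization_state.value}")
    scaler = MinMaxScaler(E.values.min(axis=0), E.values.max(axis=0))
    return (replace(E, values=scaler.transform(E.values),
                    normalization_state=NormalizationState.MINMAX), scaler)


def normalize_chain(E: ExpressionMatrix, gene_set: GeneSet | None = None
                    ) -> tuple[ExpressionMatrix, MinMaxScaler]:
    """Full preprocessing: log2 -> quantile -> (subset) -> min-max."""
    E = quantile_normalize(log2_transform(E))
    if gene_set is not None:
        E = subset_genes(E, gene_set)
    return minmax_fit_transform(E)
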