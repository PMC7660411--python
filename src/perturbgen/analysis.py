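"""Single-sample differential expression from perturbation vectors.

A trained tumor->normal generator yields, for one patient sample, a
per-gene perturbation vector ``P`` — the expression shifts needed to make
the sample look normal. Genes whose perturbation lies more than ``k``
standard deviations from the vector's own mean (default k = 2) are called
significant; this is the method's surrogate for differential expression
when only a single unreplicated sample exists (the "n = 1" problem).

Direction naming follows the tumor-reference convention: under a
tumor->normal perturbation, a POSITIVE shift means the gene had to be
raised to look normal, i.e. it is expressed LOWER in the tumor
("tumor-downregulated"); a negative shift marks a "tumor-upregulated"
gene. Under normal->tumor semantics the mapping flips. All outputs carry
both the raw sign and the tumor-relative label.

Also here: cross-patient overlap of significant-gene lists (shared genes
over the union of both lists), and the overlap of a per-sample gene list
with a cohort-level differential-expression table (consumed, never
computed: any table with gene, log2 fold change and adjusted p-value).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionSemantics",
    "SignificanceResult",
    "DGETable",
    "read_dge_table",
    "significant_genes",
    "rank_gene_extremes",
    "overlap_ratio",
    "pairwise_overlap_matrix",
    "dge_overlap",
    "perturbation_histogram",
]


class DirectionSemantics(str, enum.Enum):
    TUMOR_TO_NORMAL = "tumor_to_normal"
    NORMAL_TO_TUMOR = "normal_to_tumor"


@dataclass
class SignificanceResult:
    """Significant genes of one sample's perturbation vector.

    ``positive_genes`` / ``negative_genes`` hold genes with
    ``P > mean + k*sd`` / ``P < mean - k*sd`` (strict, population SD over
    the gene axis), each sorted by distance from the mean, descending.
    """

    sample_id: str
    perturbation: pd.Series
    mean: float
    sd: float
    k: float
    positive_genes: list[str]
    negative_genes: list[str]
    direction_semantics: DirectionSemantics

    @property
    def tumor_upregulated(self) -> list[str]:
        """Genes expressed higher in tumor than normal."""
        if self.direction_semantics is DirectionSemantics.TUMOR_TO_NORMAL:
            return self.negative_genes
        return self.positive_genes

    @property
    def tumor_downregulated(self) -> list[str]:
        """Genes expressed lower in tumor than normal."""
        if self.direction_semantics is DirectionSemantics.TUMOR_TO_NORMAL:
            return self.positive_genes
        return self.negative_genes

    def to_frame(self) -> pd.DataFrame:
        """Long table: gene, perturbation, raw sign, tumor-relative label."""
        rows = []
        up = set(self.tumor_upregulated)
        for g in self.positive_genes + self.negative_genes:
            rows.append({
                "gene": g,
                "perturbation": float(self.perturbation[g]),
                "sign": "positive" if g in self.positive_genes else "negative",
                "tumor_direction": "tumor-upregulated" if g in up
                                   else "tumor-downregulated",
            })
        return pd.DataFrame(rows, columns=["gene", "perturbation", "sign",
                                           "tumor_direction"])


def _as_series(P, gene_ids=None) -> pd.Series:
    if isinstance(P, pd.Series):
        return P.astype(float)
    P = np.asarray(P, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(P.size)]
    return pd.Series(P, index=list(gene_ids), dtype=float)


def significant_genes(P, k: float = 2.0,
                      semantics: DirectionSemantics | str = DirectionSemantics.TUMOR_TO_NORMAL,
                      gene_ids: list[str] | None = None,
                      sample_id: str = "sample") -> SignificanceResult:
    """Flag genes perturbed more than ``k`` SDs from the vector's mean.

    Mean and SD are computed over all genes of this single sample's
    perturbation vector (population SD); thresholds are strict. A constant
    vector has SD 0, so both lists come back empty (with a warning when
    k > 0).
    """
    s = _as_series(P, gene_ids)
    if s.size < 2:
        raise ValueError("significance needs >= 2 genes")
    if k < 0:
        raise ValueError("k must be >= 0")
    semantics = DirectionSemantics(semantics)
    mean = float(s.mean())
    sd = float(s.std(ddof=0))
    if sd <= 1e-14 * max(1.0, abs(mean)) and k > 0:
        logger.warning("sample %s: constant perturbation vector, no "
                       "significant genes", sample_id)
    dev = (s - mean).abs()
    pos = s.index[s > mean + k * sd]
    neg = s.index[s < mean - k * sd]
    order = dev.sort_values(ascending=False, kind="mergesort").index
    pos_sorted = [g for g in order if g in set(pos)]
    neg_sorted = [g for g in order if g in set(neg)]
    return SignificanceResult(
        sample_id=sample_id, perturbation=s, mean=mean, sd=sd, k=float(k),
        positive_genes=pos_sorted, negative_genes=neg_sorted,
        direction_semantics=semantics)


def rank_gene_extremes(P, n_top: int, direction: str,
                       gene_ids: list[str] | None = None) -> list[str]:
    """The ``n_top`` most positively ("up") or negatively ("down")
    perturbed genes, ties broken by gene id."""
    s = _as_series(P, gene_ids)
    if n_top > s.size:
        raise ValueError(f"n_top={n_top} exceeds gene count {s.size}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    df = pd.DataFrame({"P": s.to_numpy(), "gene": s.index})
    ascending = direction == "down"
    df = df.sort_values(["P", "gene"], ascending=[ascending, True],
                        kind="mergesort")
    return df["gene"].head(n_top).tolist()


def overlap_ratio(A, B) -> tuple[float, int, int]:
    """Shared genes over the union of both lists: (ratio, |A∩B|, |A∪B|)."""
    A, B = set(A), set(B)
    shared = len(A & B)
    union = len(A | B)
    return (shared / union if union else 0.0, shared, union)


@dataclass
class OverlapMatrix:
    ratio: pd.DataFrame
    n_shared: pd.DataFrame
    n_union: pd.DataFrame


def pairwise_overlap_matrix(results: list[SignificanceResult],
                            direction: str = "tumor_up") -> OverlapMatrix:
    """All-pairs overlap of the chosen-direction gene lists.

    ``direction`` is "tumor_up" or "tumor_down". Diagonal entries are 1
    (or 0 for an empty list). The ratio frame is symmetric.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 results to compare")
    if direction == "tumor_up":
        lists = [r.tumor_upregulated for r in results]
    elif direction == "tumor_down":
        lists = [r.tumor_downregulated for r in results]
    else:
        raise ValueError(f"direction must be 'tumor_up' or 'tumor_down', got {direction!r}")
    ids = [r.sample_id for r in results]
    n = len(ids)
    ratio = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    union = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            ratio[i, j], shared[i, j], union[i, j] = overlap_ratio(lists[i], lists[j])
    return OverlapMatrix(
        ratio=pd.DataFrame(ratio, index=ids, columns=ids),
        n_shared=pd.DataFrame(shared, index=ids, columns=ids),
        n_union=pd.DataFrame(union, index=ids, columns=ids))


def export_overlap_heatmap(matrix: OverlapMatrix, path) -> None:
    """Render the pairwise overlap ratios as an annotated heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(1.0 + matrix.ratio.shape[0],
                                    0.8 + matrix.ratio.shape[0]))
    sns.heatmap(matrix.ratio, annot=True, fmt=".2f", vmin=0, vmax=1,
                cmap="viridis", ax=ax)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# -- external DGE comparison --------------------------------------------


@dataclass
class DGETable:
    """Cohort-level differential-expression results (consumed, not computed)."""

    table: pd.DataFrame  # columns: gene_id, log2_fold_change, adjusted_p

    def __post_init__(self) -> None:
        need = {"gene_id", "log2_fold_change", "adjusted_p"}
        if not need <= set(self.table.columns):
            raise ValueError(f"DGE table needs columns {sorted(need)}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in DGE table: {dups.head().tolist()}")
        p = self.table["adjusted_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")

    def significant(self, alpha: float, sign: str) -> set[str]:
        """Genes with adjusted_p < alpha and the given fold-change sign."""
        t = self.table
        mask = t["adjusted_p"] < alpha
        if sign == "positive":
            mask &= t["log2_fold_change"] > 0
        elif sign == "negative":
            mask &= t["log2_fold_change"] < 0
        else:
            raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
        return set(t.loc[mask, "gene_id"])


_DGE_ALIASES = {
    "gene": "gene_id", "gene_id": "gene_id", "geneid": "gene_id",
    "log2foldchange": "log2_fold_change", "log2_fold_change": "log2_fold_change",
    "log2fc": "log2_fold_change", "lfc": "log2_fold_change",
    "padj": "adjusted_p", "adjusted_p": "adjusted_p", "p_adj": "adjusted_p",
    "fdr": "adjusted_p",
}


def read_dge_table(path) -> DGETable:
    """Read a tab-delimited DGE table; DESeq2-style column names accepted."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _DGE_ALIASES:
            rename[col] = _DGE_ALIASES[key]
    df = df.rename(columns=rename)
    df = df.dropna(subset=[c for c in ("log2_fold_change", "adjusted_p")
                           if c in df.columns])
    return DGETable(df[["gene_id", "log2_fold_change", "adjusted_p"]].copy())


def dge_overlap(result: SignificanceResult, dge: DGETable,
                alpha: float = 1e-4, direction: str = "tumor_up"
                ) -> tuple[float, int, int]:
    """Fraction of a sample's significant genes confirmed by cohort DGE.

    Tumor-upregulated genes are compared with the positive-fold-change DGE
    set, tumor-downregulated with the negative set. Returns
    ``(percentage, n_shared, n_sample_genes)``, the "x% (n/m)" convention.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if direction == "tumor_up":
        genes = result.tumor_upregulated
        dge_set = dge.significant(alpha, "positive")
    elif direction == "tumor_down":
        genes = result.tumor_downregulated
        dge_set = dge.significant(alpha, "negative")
    else:
        raise ValueError(f"direction must be 'tumor_up' or 'tumor_down', got {direction!r}")
    if not genes:
        logger.warning("sample %s: empty %s gene list, DGE overlap undefined",
                       result.sample_id, direction)
        return 0.0, 0, 0
    shared = len(set(genes) & dge_set)
    return 100.0 * shared / len(genes), shared, len(genes)


def format_dge_overlap(percentage: float, n_shared: int, n_total: int) -> str:
    return f"{percentage:.1f}% ({n_shared}/{n_total})"


def perturbation_histogram(result_a: SignificanceResult,
                           result_b: SignificanceResult,
                           path) -> dict:
    """Overlay the two perturbation distributions; return summary stats.

    The summary carries each vector's SD and its count of genes beyond
    mean ± 2 SD — the null-contrast quantities (a sample already in the
    target state should show a much tighter perturbation distribution).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if list(result_a.perturbation.index) != list(result_b.perturbation.index):
        raise ValueError("results cover different gene universes")

    def _stats(res: SignificanceResult) -> dict:
        s = res.perturbation
        mean = float(s.mean())
        sd = float(s.std(ddof=0))
        n_sig = int(((s - mean).abs() > 2 * sd).sum()) if sd > 0 else 0
        return {"sample_id": res.sample_id, "mean": mean, "sd": sd,
                "n_beyond_2sd": n_sig}

    summary = {"a": _stats(result_a), "b": _stats(result_b)}
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(result_a.perturbation, bins=50, alpha=0.6,
            label=result_a.sample_id)
    ax.hist(result_b.perturbation, bins=50, alpha=0.6,
            label=result_b.sample_id)
    ax.set_xlabel("perturbation")
    ax.set_ylabel("genes")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return summary
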