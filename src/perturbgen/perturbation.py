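"""Applying a trained generator: adversarial samples, validity, summaries.

A perturbation record holds, for one sample, the original vector ``x`` in
[0,1], the generator output ``P = G(x)`` in [-1,1], the clipped adversarial
sample ``x_adv = clip(x + P, 0, 1)``, and whether the frozen classifier
assigns ``x_adv`` to the requested target class (the validity criterion).
Attack success over a set of records is the fraction of valid ones,
reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gem_io import ExpressionMatrix
from .networks import apply_generator
from .nn import Sequential
from .training import TargetModel

__all__ = [
    "PerturbationRecord",
    "perturb_sample",
    "perturb_matrix",
    "attack_success_rate",
    "naive_difference",
    "export_heatmap_panel",
    "tsne_embedding",
]


@dataclass
class PerturbationRecord:
    sample_id: str
    x: np.ndarray
    P: np.ndarray
    x_adv: np.ndarray
    source_label: str | None
    target_label: str
    predicted_label: str
    valid: bool

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.x_adv = np.asarray(self.x_adv, dtype=float)
        if not (self.x.shape == self.P.shape == self.x_adv.shape):
            raise ValueError("x, P and x_adv must have equal length")
        if (self.x < 0).any() or (self.x > 1).any():
            raise ValueError("x must lie in [0, 1]")
        if (np.abs(self.P) > 1.0 + 1e-12).any():
            raise ValueError("P must lie in [-1, 1]")
        if (self.x_adv < 0).any() or (self.x_adv > 1).any():
            raise ValueError("x_adv must lie in [0, 1]")
        if self.valid != (self.predicted_label == self.target_label):
            raise ValueError("valid flag inconsistent with predicted/target labels")


def perturb_sample(G: Sequential, f: TargetModel, x: np.ndarray,
                   sample_id: str = "sample", source_label: str | None = None,
                   target_label: str = "") -> PerturbationRecord:
    """Perturb one sample toward ``target_label`` and validate it.

    ``P`` is stored before clipping; ``x_adv`` is the clipped sum.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(f.gene_ids):
        raise ValueError(
            f"gene-order mismatch: sample has {x.size} genes, model expects "
            f"{len(f.gene_ids)}")
    P = apply_generator(G, x)
    x_adv = np.clip(x + P, 0.0, 1.0)
    predicted = str(f.predict_labels(x_adv)[0])
    return PerturbationRecord(
        sample_id=str(sample_id), x=x, P=P, x_adv=x_adv,
        source_label=source_label, target_label=str(target_label),
        predicted_label=predicted, valid=predicted == str(target_label))


def perturb_matrix(G: Sequential, f: TargetModel, E: ExpressionMatrix,
                   target_label: str) -> list[PerturbationRecord]:
    """Perturb every sample of ``E`` toward the target class.

    The generator and classifier run once on the full batch; records are
    identical to per-sample calls because inference mode is deterministic.
    """
    labels = E.labels or {}
    P = apply_generator(G, E.values)
    x_adv = np.clip(E.values + P, 0.0, 1.0)
    predicted = f.predict_labels(x_adv)
    return [
        PerturbationRecord(
            sample_id=sid, x=E.values[i], P=P[i], x_adv=x_adv[i],
            source_label=labels.get(sid), target_label=str(target_label),
            predicted_label=str(predicted[i]),
            valid=str(predicted[i]) == str(target_label))
        for i, sid in enumerate(E.sample_ids)
    ]


def attack_success_rate(records: list[PerturbationRecord]) -> float:
    """Percentage of records the classifier assigns to the target class."""
    if not records:
        raise ValueError("attack_success_rate needs a non-empty record list")
    targets = {r.target_label for r in records}
    if len(targets) != 1:
        raise ValueError(f"records mix target classes: {sorted(targets)}")
    return 100.0 * sum(r.valid for r in records) / len(records)


def naive_difference(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Elementwise difference between two expression vectors."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a - b


def export_heatmap_panel(record: PerturbationRecord, mu_t: np.ndarray,
                         path, gene_ids: list[str] | None = None) -> None:
    """Write the (x, P, x_adv, mu_t) panel as an image plus a TSV.

    x / x_adv / mu_t share a [0,1] sequential color scale; P uses a
    [-1,1] diverging scale. The TSV carries the exact numbers. Validity
    and clipping consistency are re-checked before anything is written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mu_t = np.asarray(mu_t, dtype=float)
    if mu_t.shape != record.x.shape:
        raise ValueError("mu_t length does not match the record's vectors")
    if not np.allclose(record.x_adv, np.clip(record.x + record.P, 0.0, 1.0)):
        raise ValueError("stale record: x_adv != clip(x + P, 0, 1)")
    if record.valid != (record.predicted_label == record.target_label):
        raise ValueError("stale record: validity flag inconsistent")

    import pandas as pd
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(record.x.size)]
    table = pd.DataFrame([record.x, record.P, record.x_adv, mu_t],
                         index=["x", "P", "x_adv", "mu_t"], columns=genes)
    tsv_path = str(path) + ".tsv" if not str(path).endswith(".tsv") else str(path)
    table.to_csv(tsv_path, sep="\t", float_format=None)

    fig, axes = plt.subplots(4, 1, figsize=(10, 4), sharex=True)
    for ax, (name, row) in zip(axes, table.iterrows()):
        if name == "P":
            ax.imshow(row.to_numpy()[None, :], aspect="auto", cmap="RdBu_r",
                      vmin=-1, vmax=1)
        else:
            ax.imshow(row.to_numpy()[None, :], aspect="auto", cmap="viridis",
                      vmin=0, vmax=1)
        ax.set_yticks([0])
        ax.set_yticklabels([name])
        ax.set_xticks([])
    axes[0].set_title(f"{record.sample_id}: "
                      f"{record.source_label} -> {record.target_label} "
                      f"({'valid' if record.valid else 'invalid'})")
    img_path = str(path) if str(path).endswith(".png") else str(path) + ".png"
    fig.savefig(img_path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def tsne_embedding(values: np.ndarray, seed: int = 0, perplexity: float = 30.0
                   ) -> np.ndarray:
    """2-D t-SNE embedding (library-delegated visualization plumbing)."""
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, max(2.0, (values.shape[0] - 1) / 3.0))
    return TSNE(n_components=2, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(values)
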