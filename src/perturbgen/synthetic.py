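"""Synthetic gene expression matrices for end-to-end testing at desk scale.

Two generators are provided:

* :func:`simulate_gem` — a multi-class GEM mimicking the strong tissue
  signal of large expression atlases: each class gets its own per-gene mean
  vector drawn uniformly on the [0, 1] expression scale, and samples are
  the class mean plus i.i.d. Gaussian noise, clipped to [0, 1]. Classes are
  therefore linearly separable at moderate noise.
* :func:`simulate_paired_tumor` — a two-class "normal"/"tumor" GEM where
  the tumor class equals the normal class except for planted up- and
  down-regulated gene programs of known effect size. The planted truth is
  the ground reference for recovering per-sample differential genes.

Simulation happens directly on the [0, 1] min-max scale the networks
consume; no attempt is made to imitate raw RNA-seq count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gem_io import ExpressionMatrix, NormalizationState

__all__ = [
    "SimulationSpec",
    "PlantedTruth",
    "simulate_gem",
    "simulate_paired_tumor",
    "make_planted_truth",
]


@dataclass
class SimulationSpec:
    """Parameters of the multi-class simulation.

    Defaults are the package's standard desk-scale benchmark: 10 classes x
    50 samples x 200 genes with noise sd 0.05, class means uniform on
    [0.1, 0.9] so noise rarely pushes values against the [0, 1] clip.
    """

    n_classes: int = 10
    n_genes: int = 200
    samples_per_class: int = 50
    class_mean_low: float = 0.1
    class_mean_high: float = 0.9
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.class_mean_low < self.class_mean_high <= 1.0):
            raise ValueError("need 0 <= class_mean_low < class_mean_high <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PlantedTruth:
    """Ground-truth differential gene programs planted in the tumor class."""

    up_genes: list[str]
    down_genes: list[str]
    delta: float

    def __post_init__(self) -> None:
        self.up_genes = list(self.up_genes)
        self.down_genes = list(self.down_genes)
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up_genes and down_genes must be disjoint")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must be in (0, 1]")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _assemble(class_means: np.ndarray, class_names: list[str],
              spec: SimulationSpec, rng: np.random.Generator) -> ExpressionMatrix:
    n_c = len(class_names)
    n = spec.samples_per_class
    values = np.empty((n_c * n, spec.n_genes))
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for c, name in enumerate(class_names):
        noise = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes)) \
            if spec.noise_sd > 0 else np.zeros((n, spec.n_genes))
        values[c * n:(c + 1) * n] = np.clip(class_means[c] + noise, 0.0, 1.0)
        for j in range(n):
            sid = f"{name}_s{j:03d}"
            sample_ids.append(sid)
            labels[sid] = name
    return ExpressionMatrix(values, _gene_ids(spec.n_genes), sample_ids,
                            labels, NormalizationState.MINMAX)


def simulate_gem(spec: SimulationSpec,
                 return_class_means: bool = False):
    """Draw a multi-class GEM; fully reproducible from ``spec.seed``.

    Class means are drawn before any noise, so rerunning with the same
    seed and ``noise_sd=0`` reproduces the exact class-mean matrix.
    """
    rng = np.random.default_rng(spec.seed)
    class_means = rng.uniform(spec.class_mean_low, spec.class_mean_high,
                              size=(spec.n_classes, spec.n_genes))
    names = [f"class_{c}" for c in range(spec.n_classes)]
    E = _assemble(class_means, names, spec, rng)
    if return_class_means:
        return E, class_means
    return E


def make_planted_truth(spec: SimulationSpec, n_up: int = 10, n_down: int = 10,
                       delta: float = 0.4) -> PlantedTruth:
    """Pick disjoint up/down gene programs deterministically from the seed."""
    if n_up + n_down > spec.n_genes:
        raise ValueError("more planted genes than genes in the simulation")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    chosen = rng.choice(spec.n_genes, size=n_up + n_down, replace=False)
    ids = _gene_ids(spec.n_genes)
    return PlantedTruth(up_genes=[ids[i] for i in chosen[:n_up]],
                        down_genes=[ids[i] for i in chosen[n_up:]],
                        delta=delta)


def simulate_paired_tumor(base: SimulationSpec, truth: PlantedTruth
                          ) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-class "normal"/"tumor" GEM with planted differential programs.

    The tumor mean equals the normal mean shifted by +delta on the up
    program and -delta on the down program (clipped to [0, 1]); every other
    gene is identical in expectation between the classes.
    """
    ids = _gene_ids(base.n_genes)
    pos = {g: i for i, g in enumerate(ids)}
    unknown = [g for g in truth.up_genes + truth.down_genes if g not in pos]
    if unknown:
        raise ValueError(f"planted genes not in simulated gene ids: {unknown[:5]}")
    rng = np.random.default_rng(base.seed)
    normal_mean = rng.uniform(base.class_mean_low, base.class_mean_high,
                              size=base.n_genes)
    tumor_mean = normal_mean.copy()
    tumor_mean[[pos[g] for g in truth.up_genes]] += truth.delta
    tumor_mean[[pos[g] for g in truth.down_genes]] -= truth.delta
    tumor_mean = np.clip(tumor_mean, 0.0, 1.0)
    spec2 = SimulationSpec(n_classes=2, n_genes=base.n_genes,
                           samples_per_class=base.samples_per_class,
                           class_mean_low=base.class_mean_low,
                           class_mean_high=base.class_mean_high,
                           noise_sd=base.noise_sd, seed=base.seed)
    E = _assemble(np.stack([normal_mean, tumor_mean]), ["normal", "tumor"],
                  spec2, rng)
    return E, truth
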