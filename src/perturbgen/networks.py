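"""The three networks of the perturbation GAN and its four loss terms.

The model is an AdvGAN-style targeted attack on a transcriptome classifier:

* generator ``G`` maps a [0,1]-scaled expression sample ``x`` to an
  additive per-gene perturbation ``P = G(x)`` in [-1, 1] (tanh output);
  the adversarial sample is ``x_adv = x + P``;
* discriminator ``D`` scores whether a sample looks drawn from the target
  class (least-squares GAN objective, single linear output);
* target model ``f`` is a softmax tissue/tumor classifier, trained first
  and frozen; the generator must make ``f`` assign ``x_adv`` to a chosen
  target class ``t``.

Generator loss (default weights 1 each):

    L = L_GAN + L_adv + L_norm + L_td

with the least-squares GAN term, the Carlini-Wagner margin
``L_adv = mean_s max(max_{i != t} f(x_adv)_i - f(x_adv)_t, kappa)`` on
pre-softmax logits (kappa = 0 by default), the perturbation norm
``L_norm = mean_s ||P_s||_2``, and the target-distribution anchor
``L_td = mean_s mean_g |x_adv - r_t|`` with ``r_t ~ N(mu_t, Sigma_t)``
drawn per sample from diagonal per-gene target-class statistics.

Each public loss function has a ``*_grad`` companion returning the exact
gradient used by the training loop; the pure functions double as logging
and as oracles in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gem_io import ExpressionMatrix
from .nn import (Adam, BatchNorm, Dense, LeakyReLU, ReLU, ResidualBlock,
                 Sequential, Tanh)

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TargetModelConfig",
    "LossWeights",
    "LossBreakdown",
    "ClassStats",
    "build_generator",
    "build_discriminator",
    "build_target_model",
    "apply_generator",
    "gan_losses",
    "adversarial_loss",
    "norm_loss",
    "target_distribution_loss",
    "total_generator_loss",
    "class_stats",
    "sample_target_vector",
    "softmax",
    "save_network",
    "load_network_arrays",
]


# -- configurations -----------------------------------------------------


@dataclass
class GeneratorConfig:
    """Hourglass generator: 512/256/128 encoder, 3 residual blocks of width
    128, 256/512 decoder, tanh output of the input dimension. Hidden dense
    layers carry batch norm + ReLU; the output layer has neither (batch
    norm would fight the tanh bound)."""

    encoder_widths: tuple[int, ...] = (512, 256, 128)
    n_residual_blocks: int = 3
    decoder_widths: tuple[int, ...] = (256, 512)
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.encoder_widths + self.decoder_widths):
            raise ValueError("layer widths must be positive")
        if self.n_residual_blocks < 0:
            raise ValueError("n_residual_blocks must be >= 0")


@dataclass
class DiscriminatorConfig:
    """512/256/128 dense stack, batch norm + leaky ReLU (alpha 0.2), one
    linear output unit (required by the least-squares objective)."""

    widths: tuple[int, ...] = (512, 256, 128)
    leaky_alpha: float = 0.2
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("layer widths must be positive")


@dataclass
class TargetModelConfig:
    """1024/512/128 dense stack with plain ReLU; one linear logit per
    class, softmax applied only for probability/label prediction."""

    widths: tuple[int, ...] = (1024, 512, 128)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ValueError("layer widths must be positive")


@dataclass
class LossWeights:
    w_gan: float = 1.0
    w_adv: float = 1.0
    w_norm: float = 1.0
    w_td: float = 1.0
    kappa: float = 0.0
    #: compute the adversarial margin on softmax probabilities instead of
    #: raw logits (the margin's source formulation uses logits)
    adv_on_probs: bool = False
    #: L_td reduction over genes: "sum" is the raw L1 distance (the formula
    #: as written, and the anchor strength the near-perfect attack rates
    #: rely on); "mean" rescales by gene count for gene-set-size-independent
    #: loss balance
    td_reduction: str = "sum"

    def __post_init__(self) -> None:
        if min(self.w_gan, self.w_adv, self.w_norm, self.w_td) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.td_reduction not in ("sum", "mean"):
            raise ValueError("td_reduction must be 'sum' or 'mean'")


@dataclass
class LossBreakdown:
    """The four generator loss terms and their weighted total for one
    minibatch (or one epoch's average)."""

    L_gan: float
    L_adv: float
    L_norm: float
    L_td: float
    L_total: float

    @classmethod
    def from_parts(cls, L_gan: float, L_adv: float, L_norm: float,
                   L_td: float, w: LossWeights | None = None) -> "LossBreakdown":
        w = w or LossWeights()
        total = (w.w_gan * L_gan + w.w_adv * L_adv
                 + w.w_norm * L_norm + w.w_td * L_td)
        return cls(float(L_gan), float(L_adv), float(L_norm), float(L_td),
                   float(total))


@dataclass
class ClassStats:
    """Per-gene mean and variance (diagonal covariance) of a target class.

    Population variance convention (divide by n). With genes far
    outnumbering samples a full covariance is singular, so target vectors
    are sampled gene-wise from the diagonal by default; full-covariance
    sampling is available via ``full_cov`` in :func:`class_stats`.
    """

    label: str
    mu: np.ndarray
    sigma_diag: np.ndarray
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_diag = np.asarray(self.sigma_diag, dtype=float)
        if self.mu.shape != self.sigma_diag.shape:
            raise ValueError("mu and sigma_diag must have equal length")
        if (self.sigma_diag < 0).any():
            raise ValueError("variances must be non-negative")


# -- network builders ---------------------------------------------------


def build_generator(n_genes: int, rng: np.random.Generator,
                    config: GeneratorConfig | None = None) -> Sequential:
    cfg = config or GeneratorConfig()
    layers: list = []
    prev = n_genes
    for w in cfg.encoder_widths:
        layers += [Dense(prev, w, rng, init="he"),
                   BatchNorm(w, momentum=cfg.bn_momentum), ReLU()]
        prev = w
    for _ in range(cfg.n_residual_blocks):
        layers.append(ResidualBlock(prev, rng, momentum=cfg.bn_momentum))
    for w in cfg.decoder_widths:
        layers += [Dense(prev, w, rng, init="he"),
                   BatchNorm(w, momentum=cfg.bn_momentum), ReLU()]
        prev = w
    layers += [Dense(prev, n_genes, rng, init="glorot"), Tanh()]
    return Sequential(layers)


def build_discriminator(n_genes: int, rng: np.random.Generator,
                        config: DiscriminatorConfig | None = None) -> Sequential:
    cfg = config or DiscriminatorConfig()
    layers: list = []
    prev = n_genes
    for w in cfg.widths:
        layers += [Dense(prev, w, rng, init="he"),
                   BatchNorm(w, momentum=cfg.bn_momentum),
                   LeakyReLU(cfg.leaky_alpha)]
        prev = w
    layers.append(Dense(prev, 1, rng, init="glorot"))
    return Sequential(layers)


def build_target_model(n_genes: int, n_classes: int, rng: np.random.Generator,
                       config: TargetModelConfig | None = None) -> Sequential:
    if n_classes < 2:
        raise ValueError("target model needs >= 2 classes")
    cfg = config or TargetModelConfig()
    layers: list = []
    prev = n_genes
    for w in cfg.widths:
        layers += [Dense(prev, w, rng, init="he"), ReLU()]
        prev = w
    layers.append(Dense(prev, n_classes, rng, init="glorot"))
    return Sequential(layers)


def apply_generator(G: Sequential, x: np.ndarray) -> np.ndarray:
    """Inference-mode perturbation ``P = G(x)``; shape-preserving.

    Accepts a single sample vector or a (batch, genes) matrix; batch-norm
    layers use frozen running statistics so the output is deterministic
    for fixed weights.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    n_in = G.layers[0].W.shape[0]
    if xb.shape[1] != n_in:
        raise ValueError(f"generator expects {n_in} genes, got {xb.shape[1]}")
    P = G.forward(xb, training=False)
    return P[0] if single else P


# -- loss terms ---------------------------------------------------------


def gan_losses(D_real: np.ndarray, D_fake: np.ndarray) -> tuple[float, float]:
    """Least-squares GAN objectives (real label 1, fake label 0, target 1).

    Returns ``(L_D, L_G_gan)`` with
    ``L_D = 1/2 mean((D_real - 1)^2) + 1/2 mean(D_fake^2)`` and
    ``L_G_gan = 1/2 mean((D_fake - 1)^2)``.
    """
    D_real = np.asarray(D_real, dtype=float).ravel()
    D_fake = np.asarray(D_fake, dtype=float).ravel()
    if D_real.size == 0 or D_fake.size == 0:
        raise ValueError("empty minibatch")
    if not (np.isfinite(D_real).all() and np.isfinite(D_fake).all()):
        raise ValueError("non-finite discriminator outputs")
    L_D = 0.5 * np.mean((D_real - 1.0) ** 2) + 0.5 * np.mean(D_fake ** 2)
    L_G = 0.5 * np.mean((D_fake - 1.0) ** 2)
    return float(L_D), float(L_G)


def gan_generator_grad(D_fake: np.ndarray) -> np.ndarray:
    """d L_G_gan / d D_fake for the least-squares generator term."""
    D_fake = np.asarray(D_fake, dtype=float)
    return (D_fake - 1.0) / D_fake.size


def gan_discriminator_grads(D_real: np.ndarray, D_fake: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(d L_D / d D_real, d L_D / d D_fake)."""
    D_real = np.asarray(D_real, dtype=float)
    D_fake = np.asarray(D_fake, dtype=float)
    return (D_real - 1.0) / D_real.size, D_fake / D_fake.size


def adversarial_loss(logits: np.ndarray, t: int, kappa: float = 0.0) -> float:
    """Targeted confidence-margin loss, mean over the minibatch.

    Per sample: ``max(max_{i != t} z_i - z_t, kappa)`` on the class scores
    ``z`` (pre-softmax logits by default). Zero exactly when the target
    class (weakly) dominates and ``kappa <= 0``.
    """
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    if z.shape[1] < 2:
        raise ValueError("need >= 2 classes")
    if not 0 <= t < z.shape[1]:
        raise ValueError(f"target index {t} out of range for {z.shape[1]} classes")
    others = np.delete(z, t, axis=1).max(axis=1)
    return float(np.mean(np.maximum(others - z[:, t], kappa)))


def adversarial_loss_grad(logits: np.ndarray, t: int, kappa: float = 0.0
                          ) -> np.ndarray:
    """Gradient of :func:`adversarial_loss` w.r.t. the logits."""
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    m, C = z.shape
    grad = np.zeros_like(z)
    masked = z.copy()
    masked[:, t] = -np.inf
    runner = masked.argmax(axis=1)
    margin = masked[np.arange(m), runner] - z[:, t]
    active = margin > kappa
    grad[np.arange(m)[active], runner[active]] = 1.0 / m
    grad[np.arange(m)[active], t] = -1.0 / m
    return grad


def norm_loss(P: np.ndarray) -> float:
    """Mean over samples of the Euclidean norm of the perturbation."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    return float(np.mean(np.linalg.norm(P, axis=1)))


def norm_loss_grad(P: np.ndarray) -> np.ndarray:
    P = np.atleast_2d(np.asarray(P, dtype=float))
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return np.where(norms > 0, P / safe, 0.0) / P.shape[0]


def target_distribution_loss(x_adv: np.ndarray, r_t: np.ndarray,
                             reduction: str = "sum") -> float:
    """L1 anchor to a sampled target vector.

    ``reduction="sum"`` (default) is the raw L1 distance
    ``sum_g |x_adv,g - r_t,g|``; ``"mean"`` divides by the gene count so
    the term's scale is independent of gene-set size. Minibatches average
    over samples.
    """
    a = np.atleast_2d(np.asarray(x_adv, dtype=float))
    r = np.atleast_2d(np.asarray(r_t, dtype=float))
    if a.shape != r.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {r.shape}")
    l1 = np.abs(a - r).sum(axis=1)
    if reduction == "mean":
        l1 = l1 / a.shape[1]
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(np.mean(l1))


def target_distribution_loss_grad(x_adv: np.ndarray, r_t: np.ndarray,
                                  reduction: str = "sum") -> np.ndarray:
    a = np.atleast_2d(np.asarray(x_adv, dtype=float))
    r = np.atleast_2d(np.asarray(r_t, dtype=float))
    g = np.sign(a - r) / a.shape[0]
    if reduction == "mean":
        g = g / a.shape[1]
    return g


def total_generator_loss(parts: LossBreakdown, w: LossWeights | None = None
                         ) -> float:
    """Weighted sum of the four terms (plain sum at default weights)."""
    w = w or LossWeights()
    return float(w.w_gan * parts.L_gan + w.w_adv * parts.L_adv
                 + w.w_norm * parts.L_norm + w.w_td * parts.L_td)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# -- target-class statistics --------------------------------------------


def class_stats(E: ExpressionMatrix, t: str, full_cov: bool = False) -> ClassStats:
    """Per-gene mean and population variance of class ``t``'s samples.

    With ``full_cov`` the full covariance matrix is retained as well
    (eigenvalues floored at zero when sampling).
    """
    mask = E.label_array() == t
    if mask.sum() < 2:
        raise ValueError(f"class {t!r} needs >= 2 samples, has {int(mask.sum())}")
    X = E.values[mask]
    mu = X.mean(axis=0)
    var = X.var(axis=0)  # population convention
    cov = np.cov(X, rowvar=False, bias=True) if full_cov else None
    return ClassStats(label=str(t), mu=mu, sigma_diag=var, cov=cov)


def sample_target_vector(stats: ClassStats, rng: np.random.Generator | int,
                         size: int | None = None) -> np.ndarray:
    """Draw ``r_t ~ N(mu_t, Sigma_t)`` (not clipped to [0, 1]).

    Gene-wise diagonal sampling unless the stats carry a full covariance.
    ``size`` draws a (size, genes) batch with independent rows.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = (size,) if size is not None else ()
    if stats.cov is not None:
        w, V = np.linalg.eigh(stats.cov)
        L = V * np.sqrt(np.maximum(w, 0.0))
        z = rng.standard_normal(n + (stats.mu.size,))
        return stats.mu + z @ L.T
    return rng.normal(stats.mu, np.sqrt(stats.sigma_diag),
                      size=n + (stats.mu.size,))


# -- checkpointing ------------------------------------------------------


def save_network(net: Sequential, path, meta: dict | None = None) -> None:
    """Save all weights and buffers as .npz with a JSON metadata sidecar."""
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, **arrays)
    p = Path(path)
    sidecar = p.with_suffix(p.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta or {}, fh, indent=2, sort_keys=True)


def load_network_arrays(path) -> tuple[list[np.ndarray], dict]:
    """Load a checkpoint's arrays (in save order) and its metadata."""
    with np.load(path) as data:
        arrays = [data[k] for k in sorted(data.files)]
    p = Path(path)
    sidecar = p.with_suffix(p.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return arrays, meta
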