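"""Two-stage training: target classifier first, then the perturbation GAN.

Stage 1 trains the softmax classifier ``f`` (Adam, lr 0.001, 30 epochs,
minibatch 32) on a stratified 90/10 split and reports held-out accuracy.
Stage 2 freezes ``f`` and trains generator and discriminator alternately
(one D-step then one G-step per minibatch; Adam lrs 0.0002 / 0.0001,
150 epochs, minibatch 128). Real samples shown to the discriminator are
exclusively target-class training samples, so D judges membership in the
target distribution. All randomness descends from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gem_io import ExpressionMatrix
from .networks import (ClassStats, LossBreakdown, LossWeights,
                       adversarial_loss, adversarial_loss_grad,
                       apply_generator, build_discriminator, build_generator,
                       build_target_model, class_stats, gan_discriminator_grads,
                       gan_generator_grad, gan_losses, load_network_arrays,
                       norm_loss, norm_loss_grad, sample_target_vector,
                       save_network, softmax, target_distribution_loss,
                       target_distribution_loss_grad)
from .nn import Adam, Sequential

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TargetModel",
    "EpochLog",
    "split_stratified",
    "train_target_model",
    "train_generator",
    "save_target_model",
    "load_target_model",
    "save_generator",
    "load_generator",
]


@dataclass
class TrainingConfig:
    """Optimization hyperparameters for both stages (defaults are the
    standard settings of the method)."""

    lr_generator: float = 0.0002
    lr_discriminator: float = 0.0001
    lr_target: float = 0.001
    target_epochs: int = 30
    target_batch: int = 32
    gan_epochs: int = 150
    gan_batch: int = 128
    target_holdout_fraction: float = 0.10
    gan_holdout_fraction: float = 0.20
    seed: int = 0
    target_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.target_holdout_fraction < 1
                and 0 < self.gan_holdout_fraction < 1):
            raise ValueError("holdout fractions must be in (0, 1)")
        if min(self.target_epochs, self.target_batch,
               self.gan_epochs, self.gan_batch) < 1:
            raise ValueError("epochs and batch sizes must be >= 1")
        if min(self.lr_generator, self.lr_discriminator, self.lr_target) <= 0:
            raise ValueError("learning rates must be > 0")


@dataclass
class EpochLog:
    """One epoch's average losses and training-minibatch attack success."""

    epoch: int
    breakdown: LossBreakdown
    L_D: float
    attack_success: float


class TargetModel:
    """Trained classifier wrapper: network + class names + gene order."""

    def __init__(self, net: Sequential, classes: list[str],
                 gene_ids: list[str]) -> None:
        self.net = net
        self.classes = list(classes)
        self.gene_ids = list(gene_ids)

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"target model expects {len(self.gene_ids)} genes, got {X.shape[1]}")
        return X

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(self._check(X), training=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(X))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_logits(X).argmax(axis=1)
        return np.array([self.classes[i] for i in idx])

    def accuracy(self, E: ExpressionMatrix) -> float:
        return float(np.mean(self.predict_labels(E.values) == E.label_array()))

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ValueError(f"unknown class {label!r}; model knows {self.classes}") from None


def _seed_rng(*path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(p) for p in path]))


def split_stratified(E: ExpressionMatrix, holdout_fraction: float, seed: int
                     ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Per-class random split into (train, holdout).

    Each class contributes floor(fraction * n) holdout samples, at least 1
    and at most n-1, so every class with >= 2 samples appears in both
    partitions; singleton classes go entirely to training with a warning.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    labels = E.label_array()
    rng = _seed_rng(seed, 11)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 1:
            logger.warning("class %s has a single sample; kept in training", cls)
            train_idx.extend(idx.tolist())
            continue
        n_test = int(np.floor(holdout_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    mask = np.zeros(E.n_samples, dtype=bool)
    mask[train_idx] = True
    train = E.select_samples(mask)
    test = E.select_samples(~mask)
    return train, test


def _minibatches(n: int, batch: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch):
        yield perm[start:start + batch]


def train_target_model(E: ExpressionMatrix, config: TrainingConfig
                       ) -> tuple[TargetModel, float]:
    """Train the classifier on a stratified 90/10 split of ``E``.

    Categorical cross-entropy on softmax outputs; returns the model and
    its held-out accuracy.
    """
    classes = E.classes()
    if len(classes) < 2:
        raise ValueError("target model training needs >= 2 classes")
    train, holdout = split_stratified(E, config.target_holdout_fraction,
                                      config.seed)
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_index[l] for l in train.label_array()])
    X = train.values
    net = build_target_model(E.n_genes, len(classes), _seed_rng(config.seed, 21))
    opt = Adam(net, lr=config.lr_target)
    onehot = np.eye(len(classes))[y]
    for epoch in range(config.target_epochs):
        rng_e = _seed_rng(config.seed, 22, epoch)
        for batch in _minibatches(X.shape[0], config.target_batch, rng_e):
            logits = net.forward(X[batch], training=True)
            probs = softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(batch.size), y[batch]] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite target-model loss at epoch {epoch}: {loss}")
            opt.zero_grad()
            net.backward((probs - onehot[batch]) / batch.size)
            opt.step()
    model = TargetModel(net, classes, E.gene_ids)
    return model, model.accuracy(holdout)


def train_generator(E_train: ExpressionMatrix, f: TargetModel,
                    config: TrainingConfig,
                    loss_weights: LossWeights | None = None
                    ) -> tuple[Sequential, Sequential, list[EpochLog]]:
    """Adversarial training of generator G and discriminator D against the
    frozen classifier ``f``.

    Per minibatch: one discriminator step on (real target-class samples,
    current adversarial samples), then one generator step on the full
    four-term objective. ``f``'s weights are never touched. Returns
    ``(G, D, per-epoch loss log)``.
    """
    w = loss_weights or LossWeights()
    target = config.target_class
    if target is None:
        raise ValueError("config.target_class must be set")
    labels = E_train.label_array()
    if target not in labels:
        raise ValueError(f"target class {target!r} absent from training labels")
    t_idx = f.class_index(target)
    stats = class_stats(E_train, target)
    n_genes = E_train.n_genes
    if n_genes != len(f.gene_ids):
        raise ValueError("gene order mismatch between data and target model")

    G = build_generator(n_genes, _seed_rng(config.seed, 31))
    D = build_discriminator(n_genes, _seed_rng(config.seed, 32))
    optG = Adam(G, lr=config.lr_generator)
    optD = Adam(D, lr=config.lr_discriminator)
    X = E_train.values
    real_pool = X[labels == target]
    log: list[EpochLog] = []

    for epoch in range(config.gan_epochs):
        rng_e = _seed_rng(config.seed, 33, epoch)
        sums = np.zeros(4)  # L_gan, L_adv, L_norm, L_td
        sum_LD = 0.0
        sum_hits = 0.0
        n_batches = 0
        n_seen = 0
        for batch in _minibatches(X.shape[0], config.gan_batch, rng_e):
            x = X[batch]
            m = x.shape[0]
            P = G.forward(x, training=True)
            x_adv = x + P

            # -- discriminator step (x_adv detached) --
            real = real_pool[rng_e.integers(0, real_pool.shape[0], size=m)]
            optD.zero_grad()
            d_real = D.forward(real, training=True)
            g_real, _ = gan_discriminator_grads(d_real, np.zeros(1))
            D.backward(g_real)
            d_fake_det = D.forward(x_adv, training=True, update_stats=False)
            _, g_fake = gan_discriminator_grads(np.ones(1), d_fake_det)
            D.backward(g_fake)
            optD.step()
            L_D, _ = gan_losses(d_real, d_fake_det)

            # -- generator step (through frozen D and f) --
            optG.zero_grad()
            D.zero_grad()
            f.net.zero_grad()
            d_fake = D.forward(x_adv, training=True, update_stats=False)
            grad_gan = D.backward(w.w_gan * gan_generator_grad(d_fake))
            logits = f.net.forward(x_adv, training=False)
            if w.adv_on_probs:
                probs = softmax(logits)
                gp = adversarial_loss_grad(probs, t_idx, w.kappa)
                g_adv = probs * (gp - (gp * probs).sum(axis=1, keepdims=True))
                L_adv = adversarial_loss(probs, t_idx, w.kappa)
            else:
                g_adv = adversarial_loss_grad(logits, t_idx, w.kappa)
                L_adv = adversarial_loss(logits, t_idx, w.kappa)
            grad_adv = f.net.backward(w.w_adv * g_adv)
            r_t = sample_target_vector(stats, rng_e, size=m)
            reduction = w.td_reduction
            grad_td = w.w_td * target_distribution_loss_grad(x_adv, r_t, reduction)
            grad_norm = w.w_norm * norm_loss_grad(P)
            G.backward(grad_gan + grad_adv + grad_td + grad_norm)
            optG.step()

            _, L_gan = gan_losses(d_real, d_fake)
            L_norm = norm_loss(P)
            L_td = target_distribution_loss(x_adv, r_t, reduction)
            terms = np.array([L_gan, L_adv, L_norm, L_td])
            if not np.isfinite(terms).all() or not np.isfinite(L_D):
                raise RuntimeError(
                    f"non-finite GAN loss at epoch {epoch}: "
                    f"L_gan={L_gan}, L_adv={L_adv}, L_norm={L_norm}, "
                    f"L_td={L_td}, L_D={L_D}")
            sums += terms
            sum_LD += L_D
            sum_hits += float(np.sum(logits.argmax(axis=1) == t_idx))
            n_batches += 1
            n_seen += m
        avg = sums / n_batches
        log.append(EpochLog(
            epoch=epoch,
            breakdown=LossBreakdown.from_parts(*avg, w=w),
            L_D=sum_LD / n_batches,
            attack_success=sum_hits / n_seen,
        ))
    return G, D, log


# -- checkpoint helpers -------------------------------------------------


def save_target_model(model: TargetModel, path, seed: int | None = None) -> None:
    save_network(model.net, path, meta={
        "kind": "target_model",
        "classes": model.classes,
        "gene_ids": model.gene_ids,
        "seed": seed,
    })


def load_target_model(path) -> TargetModel:
    arrays, meta = load_network_arrays(path)
    if meta.get("kind") != "target_model":
        raise ValueError(f"{path} is not a target-model checkpoint")
    net = build_target_model(len(meta["gene_ids"]), len(meta["classes"]),
                             np.random.default_rng(0))
    net.load_state_arrays(arrays)
    return TargetModel(net, meta["classes"], meta["gene_ids"])


def save_generator(G: Sequential, path, gene_ids: list[str],
                   target_class: str, seed: int | None = None) -> None:
    save_network(G, path, meta={
        "kind": "generator",
        "gene_ids": list(gene_ids),
        "target_class": target_class,
        "seed": seed,
    })


def load_generator(path) -> tuple[Sequential, dict]:
    arrays, meta = load_network_arrays(path)
    if meta.get("kind") != "generator":
        raise ValueError(f"{path} is not a generator checkpoint")
    G = build_generator(len(meta["gene_ids"]), np.random.default_rng(0))
    G.load_state_arrays(arrays)
    return G, meta
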