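"""Loss terms, class statistics and generator output guarantees.

Every loss gets its stated examples plus a brute-force oracle on random
inputs; gradients of the composite generator objective are checked against
central differences on a miniature network stack.
"""

import numpy as np
import pytest

from perturbgen.gem_io import ExpressionMatrix, NormalizationState
from perturbgen.networks import (ClassStats, LossBreakdown, LossWeights,
                                 adversarial_loss, adversarial_loss_grad,
                                 apply_generator, build_discriminator,
                                 build_generator, build_target_model,
                                 class_stats, gan_generator_grad, gan_losses,
                                 norm_loss, norm_loss_grad,
                                 sample_target_vector,
                                 target_distribution_loss,
                                 target_distribution_loss_grad,
                                 total_generator_loss)
from perturbgen.nn import (BatchNorm, Dense, LeakyReLU, ReLU, ResidualBlock,
                           Sequential, Tanh)

RNG = np.random.default_rng(1234)


# -- generator application ---------------------------------------------


def test_generator_output_bounded_and_deterministic():
    G = build_generator(20, np.random.default_rng(0))
    x = RNG.uniform(0, 1, (16, 20))
    P1 = apply_generator(G, x)
    P2 = apply_generator(G, x)
    np.testing.assert_array_equal(P1, P2)
    assert np.abs(P1).max() <= 1.0
    # bound holds for arbitrary random weights too
    for seed in range(3):
        Gr = build_generator(20, np.random.default_rng(seed))
        for p in Gr.parameters():
            p *= 50.0  # blow up weights; tanh still bounds the output
        assert np.abs(apply_generator(Gr, x)).max() <= 1.0


def test_generator_zero_final_layer_gives_zero_perturbation():
    G = build_generator(10, np.random.default_rng(0))
    final_dense = G.layers[-2]
    final_dense.W[...] = 0.0
    final_dense.b[...] = 0.0
    P = apply_generator(G, RNG.uniform(0, 1, (4, 10)))
    np.testing.assert_array_equal(P, 0.0)


def test_generator_dimension_mismatch():
    G = build_generator(10, np.random.default_rng(0))
    with pytest.raises(ValueError, match="expects 10 genes"):
        apply_generator(G, np.zeros(7))


# -- gan_losses ---------------------------------------------------------


def test_gan_losses_examples():
    L_D, L_G = gan_losses(np.array([1.0]), np.array([0.0]))
    assert L_D == 0.0 and L_G == 0.5
    L_D, L_G = gan_losses(np.array([0.0]), np.array([1.0]))
    assert L_D == 1.0 and L_G == 0.0
    with pytest.raises(ValueError, match="empty"):
        gan_losses(np.array([]), np.array([1.0]))


def test_gan_losses_random_oracle():
    for _ in range(1000):
        dr = RNG.normal(size=RNG.integers(1, 6))
        df = RNG.normal(size=RNG.integers(1, 6))
        L_D, L_G = gan_losses(dr, df)
        assert L_D == pytest.approx(
            0.5 * np.mean([(v - 1) ** 2 for v in dr])
            + 0.5 * np.mean([v ** 2 for v in df]))
        assert L_G == pytest.approx(0.5 * np.mean([(v - 1) ** 2 for v in df]))


# -- adversarial_loss ---------------------------------------------------


def test_adversarial_loss_examples():
    assert adversarial_loss(np.array([5.0, 1.0, 2.0]), 0, 0.0) == 0.0
    assert adversarial_loss(np.array([1.0, 5.0, 2.0]), 0, 0.0) == 4.0
    with pytest.raises(ValueError, match="2 classes"):
        adversarial_loss(np.array([[3.0]]), 0, 0.0)


def test_adversarial_loss_brute_force_oracle():
    for _ in range(1000):
        C = int(RNG.integers(2, 7))
        m = int(RNG.integers(1, 5))
        z = RNG.normal(size=(m, C))
        t = int(RNG.integers(0, C))
        kappa = float(RNG.uniform(-1, 1))
        expected = np.mean([
            max(max(z[s, i] for i in range(C) if i != t) - z[s, t], kappa)
            for s in range(m)])
        assert adversarial_loss(z, t, kappa) == pytest.approx(expected)


def test_adversarial_loss_zero_iff_target_argmax():
    for _ in range(200):
        z = RNG.normal(size=5)
        t = int(RNG.integers(0, 5))
        loss = adversarial_loss(z, t, 0.0)
        if z.argmax() == t:
            assert loss == 0.0
        else:
            assert loss > 0.0


# -- norm / target-distribution / total ---------------------------------


def test_norm_loss_examples_and_oracle():
    assert norm_loss(np.zeros(5)) == 0.0
    assert norm_loss(np.array([3.0, 4.0])) == 5.0
    for _ in range(1000):
        P = RNG.normal(size=(int(RNG.integers(1, 4)), int(RNG.integers(1, 8))))
        expected = np.mean([np.sqrt(sum(v * v for v in row)) for row in P])
        assert norm_loss(P) == pytest.approx(expected)


def test_target_distribution_loss_examples_and_oracle():
    x = np.array([0.0, 1.0])
    r = np.array([1.0, 0.0])
    assert target_distribution_loss(x, x) == 0.0
    assert target_distribution_loss(x, r, reduction="sum") == 2.0
    assert target_distribution_loss(x, r, reduction="mean") == 1.0
    with pytest.raises(ValueError, match="mismatch"):
        target_distribution_loss(np.zeros(3), np.zeros(4))
    for _ in range(1000):
        n = int(RNG.integers(1, 8))
        a, b = RNG.normal(size=n), RNG.normal(size=n)
        raw = sum(abs(u - v) for u, v in zip(a, b))
        assert target_distribution_loss(a, b, "sum") == pytest.approx(raw)
        assert target_distribution_loss(a, b, "mean") == pytest.approx(raw / n)


def test_total_generator_loss():
    parts = LossBreakdown.from_parts(1.0, 1.0, 1.0, 1.0)
    assert total_generator_loss(parts) == 4.0
    parts2 = LossBreakdown(1.0, 2.0, 3.0, 4.0, 0.0)
    assert total_generator_loss(parts2, LossWeights(0, 0, 0, 1)) == 4.0
    for _ in range(1000):
        vals = RNG.normal(size=4)
        w = RNG.uniform(0, 2, size=4)
        parts = LossBreakdown(*vals, 0.0)
        weights = LossWeights(*w)
        assert total_generator_loss(parts, weights) == pytest.approx(
            float(np.dot(vals, w)))


def test_loss_breakdown_invariant():
    for _ in range(100):
        vals = RNG.normal(size=4)
        w = LossWeights(*RNG.uniform(0, 2, size=4))
        parts = LossBreakdown.from_parts(*vals, w=w)
        assert abs(parts.L_total - total_generator_loss(parts, w)) < 1e-6


# -- class statistics ---------------------------------------------------


def _labeled_matrix(values, labels):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[0])]
    genes = [f"g{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples,
                            dict(zip(samples, labels)),
                            NormalizationState.MINMAX)


def test_class_stats_examples():
    E = _labeled_matrix([[0, 1], [1, 0]], ["t", "t"])
    st = class_stats(E, "t")
    np.testing.assert_allclose(st.mu, [0.5, 0.5])
    np.testing.assert_allclose(st.sigma_diag, [0.25, 0.25])  # population
    same = _labeled_matrix([[0.3, 0.7]] * 3, ["t"] * 3)
    st2 = class_stats(same, "t")
    np.testing.assert_allclose(st2.mu, [0.3, 0.7])
    np.testing.assert_allclose(st2.sigma_diag, 0.0, atol=1e-30)
    with pytest.raises(ValueError, match=">= 2 samples"):
        class_stats(_labeled_matrix([[0, 1], [1, 0]], ["t", "u"]), "t")


def test_class_stats_random_oracle():
    rng = np.random.default_rng(6)
    X = rng.uniform(0, 1, (20, 7))
    E = _labeled_matrix(X, ["a"] * 20)
    st = class_stats(E, "a")
    np.testing.assert_allclose(st.mu, [np.mean(X[:, j]) for j in range(7)])
    np.testing.assert_allclose(
        st.sigma_diag,
        [np.mean((X[:, j] - X[:, j].mean()) ** 2) for j in range(7)])


def test_sample_target_vector():
    st = ClassStats("t", np.array([0.2, 0.8]), np.array([0.0, 0.0]))
    np.testing.assert_array_equal(sample_target_vector(st, 0), st.mu)
    st2 = ClassStats("t", np.array([0.2, 0.8]), np.array([0.01, 0.04]))
    np.testing.assert_array_equal(sample_target_vector(st2, 5),
                                  sample_target_vector(st2, 5))
    draws = sample_target_vector(st2, 7, size=10_000)
    sd = np.sqrt(st2.sigma_diag)
    assert np.all(np.abs(draws.mean(axis=0) - st2.mu) < 4 * sd / 100)


# -- gradient correctness ----------------------------------------------


def test_composite_generator_gradient_matches_central_differences():
    """The hand-derived backward pass of L_GAN + L_adv + L_norm + L_td
    (through discriminator and classifier) agrees with finite differences."""
    rng = np.random.default_rng(0)
    n_genes, n_classes, m = 6, 3, 4
    G = Sequential([Dense(n_genes, 8, rng), BatchNorm(8), ReLU(),
                    ResidualBlock(8, rng),
                    Dense(8, n_genes, rng, init="glorot"), Tanh()])
    D = Sequential([Dense(n_genes, 5, rng), BatchNorm(5), LeakyReLU(0.2),
                    Dense(5, 1, rng, init="glorot")])
    F = Sequential([Dense(n_genes, 5, rng), ReLU(),
                    Dense(5, n_classes, rng, init="glorot")])
    x = rng.uniform(0, 1, (m, n_genes))
    r = rng.normal(0.5, 0.1, (m, n_genes))
    t = 1

    def total():
        P = G.forward(x, training=True)
        xa = x + P
        _, Lg = gan_losses(np.ones(m),
                           D.forward(xa, training=True, update_stats=False))
        La = adversarial_loss(F.forward(xa, training=False), t, 0.0)
        return Lg + La + norm_loss(P) + target_distribution_loss(xa, r)

    P = G.forward(x, training=True)
    xa = x + P
    G.zero_grad(); D.zero_grad(); F.zero_grad()
    d = D.forward(xa, training=True, update_stats=False)
    g = D.backward(gan_generator_grad(d))
    g = g + F.backward(adversarial_loss_grad(F.forward(xa, training=False), t, 0.0))
    g = g + target_distribution_loss_grad(xa, r)
    G.backward(g + norm_loss_grad(P))

    eps = 1e-6
    check_rng = np.random.default_rng(99)
    for p, grad in zip(G.parameters(), G.gradients()):
        for _ in range(2):
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = total()
            p[idx] = orig - eps
            lm = total()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[idx]) <= 1e-3 * max(1.0, abs(num))


def test_target_model_builder_validates_classes():
    with pytest.raises(ValueError, match="2 classes"):
        build_target_model(10, 1, np.random.default_rng(0))
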