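"""Shared fixtures: the two trained desk-scale benchmark runs.

Both fixtures are session-scoped because GAN training is the expensive
step (~1 minute each); every test that needs a trained model reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from perturbgen import (LossWeights, SimulationSpec, TrainingConfig,
                        make_planted_truth, perturb_matrix, simulate_gem,
                        simulate_paired_tumor, split_stratified,
                        train_generator, train_target_model)

BENCH_SEED = 42


@pytest.fixture(scope="session")
def multiclass_run():
    """Full pipeline on the standard 10-class benchmark, attacking class_0."""
    spec = SimulationSpec(seed=BENCH_SEED)
    E = simulate_gem(spec)
    cfg = TrainingConfig(seed=BENCH_SEED, target_class="class_0")
    f, holdout_acc = train_target_model(E, cfg)
    train, holdout = split_stratified(E, cfg.gan_holdout_fraction, cfg.seed)
    G, D, log = train_generator(train, f, cfg)
    records = perturb_matrix(G, f, holdout, "class_0")
    return {"spec": spec, "E": E, "config": cfg, "f": f,
            "holdout_accuracy": holdout_acc, "G": G, "D": D, "log": log,
            "train": train, "holdout": holdout, "records": records}


@pytest.fixture(scope="session")
def paired_run():
    """Tumor->normal pipeline on the planted-program benchmark.

    TCGA-scale cohort (250 samples/class), mid-range baseline expression,
    10 up + 10 down planted genes of effect 0.4 on the [0,1] scale.
    """
    spec = SimulationSpec(n_classes=2, n_genes=200, samples_per_class=250,
                          class_mean_low=0.3, class_mean_high=0.7,
                          noise_sd=0.05, seed=BENCH_SEED)
    truth = make_planted_truth(spec, n_up=10, n_down=10, delta=0.4)
    E, truth = simulate_paired_tumor(spec, truth)
    cfg = TrainingConfig(seed=BENCH_SEED, target_class="normal")
    f, holdout_acc = train_target_model(E, cfg)
    train, holdout = split_stratified(E, cfg.gan_holdout_fraction, cfg.seed)
    G, D, log = train_generator(train, f, cfg)
    records = perturb_matrix(G, f, holdout, "normal")
    return {"spec": spec, "truth": truth, "E": E, "config": cfg, "f": f,
            "holdout_accuracy": holdout_acc, "G": G, "log": log,
            "train": train, "holdout": holdout, "records": records,
            "tumor_records": [r for r in records if r.source_label == "tumor"],
            "normal_records": [r for r in records if r.source_label == "normal"]}
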