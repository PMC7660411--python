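"""perturbgen: adversarial perturbation generation for gene expression.

A least-squares GAN learns a per-gene additive perturbation that moves a
[0,1]-scaled expression sample from its source class into a chosen target
class of a frozen classifier; the perturbation vector doubles as a
single-sample differential-expression readout (genes shifted more than
k standard deviations from the vector's mean).
"""

from .gem_io import (ExpressionMatrix, GeneSet, MinMaxScaler,
                     NormalizationState, log2_transform, minmax_fit_transform,
                     quantile_normalize, read_gem, read_gmt, read_labels,
                     subset_genes, write_gem, write_labels)
from .synthetic import (PlantedTruth, SimulationSpec, make_planted_truth,
                        simulate_gem, simulate_paired_tumor)
from .networks import (ClassStats, DiscriminatorConfig, GeneratorConfig,
                       LossBreakdown, LossWeights, TargetModelConfig,
                       adversarial_loss, apply_generator, build_discriminator,
                       build_generator, build_target_model, class_stats,
                       gan_losses, norm_loss, sample_target_vector,
                       target_distribution_loss, total_generator_loss)
from .training import (EpochLog, TargetModel, TrainingConfig, load_generator,
                       load_target_model, save_generator, save_target_model,
                       split_stratified, train_generator, train_target_model)
from .perturbation import (PerturbationRecord, attack_success_rate,
                           naive_difference, perturb_matrix, perturb_sample)
from .analysis import (DGETable, DirectionSemantics, SignificanceResult,
                       dge_overlap, overlap_ratio, pairwise_overlap_matrix,
                       rank_gene_extremes, read_dge_table, significant_genes)

__version__ = "0.1.0"
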