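"""ssipred: semi-supervised SVM prediction of protein interface residues.

Pipeline: PDB/HSSP/Rate4Site inputs -> surface/interface labeling ->
264-dim conservation window features -> one of four learners (supervised
SVM, meanS3VM by alternating optimisation or cutting-plane MKL, safe S4VM)
-> six-metric evaluation under stratified cross-validation.
"""

from importlib import resources

from .config import KernelConfig, RunConfig, S4VMConfig, load_config
from .evaluation import ConfusionCounts, MetricReport, confusion, cross_validate, metrics, stability
from .features import (
    Standardizer,
    assemble_vector,
    conservation_weight,
    profile_frequencies,
    relative_entropy,
    residue_features,
    sequence_entropy,
    spatial_window,
)
from .io_formats import (
    N_FEATURES,
    Chain,
    FeatureVector,
    ResidueRecord,
    read_feature_table,
    read_hssp,
    read_rate4site,
    read_structure,
    write_annotated_structure,
    write_feature_table,
)
from .labeling import LabeledResidue, build_dataset, is_surface, label_interface, max_asa
from .means3vm import (
    SemiDataset,
    assign_d_by_ranking,
    augmented_kernel,
    class_mean_counts,
    estimate_r,
    means3vm_iter,
    means3vm_mkl,
    solve_given_d,
)
from .pipeline import evaluate_method, extract_features, make_learner, transductive_run
from .s4vm import (
    S4VMConfig as S4VMParams,
    SeparatorCandidate,
    diversity_penalty,
    s3vm_objective,
    s4vm_predict,
    safe_label_assignment,
    sample_separators,
    select_representatives,
)
from .svm_core import KernelSpec, SVMModel, decision_values, gram_matrix, train_supervised
from .synthetic import (
    ToySpec,
    make_confusion_random,
    make_synthetic_complex,
    make_two_gaussians,
)

__version__ = "0.1.0"

#: Confusion counts reported for chain 1A4Y_A (218 surface residues)
TABLE1_CONFUSION = {
    "means3vm-iter": ConfusionCounts(TP=57, TN=82, FP=28, FN=51),
    "means3vm-mkl": ConfusionCounts(TP=60, TN=84, FP=26, FN=48),
    "s4vm": ConfusionCounts(TP=68, TN=87, FP=23, FN=40),
}


def benchmark_chain_ids() -> list[str]:
    """The 91 non-redundant benchmark chain identifiers (PDBID_chain)."""
    text = resources.files("ssipred").joinpath("data/chains91.txt").read_text()
    return text.split()
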