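"""ecmforest: extracellular-matrix protein prediction from hybrid features.

A 315-dimensional hybrid encoding of protein sequences and auxiliary
profiles (PSSM, secondary structure, disorder, domains), information-gain-
ratio feature ranking with incremental feature selection, and an
undersampling random-forest ensemble with majority voting for the ~11:1
class imbalance between non-ECM and ECM proteins.
"""

from .io_formats import (
    AMINO_ACIDS,
    DisorderTrack,
    DomainAnnotation,
    FeatureMatrix,
    ParseError,
    ProteinRecord,
    PSSMProfile,
    SecondaryStructureTrack,
    read_fasta,
    read_feature_matrix,
    sanitize_dataset,
    write_feature_matrix,
)
from .seq_encoders import (
    DWTParams,
    PropertyScale,
    PseAACParams,
    distribution_descriptor,
    dwt_features,
    ffg_frequencies,
    pseaac,
    shannon_entropies,
    transition_descriptor,
)
from .profile_encoders import (
    AuxiliaryProfiles,
    DomainVocabulary,
    EncoderConfig,
    PSSMFeatureParams,
    build_domain_vocabulary,
    disorder_features,
    encode_all,
    encode_dataset,
    fdi_vector,
    pssm_features,
    ss_features,
)
from .feature_selection import (
    DiscretizationRule,
    IFSTrace,
    RankedFeatureList,
    ifs_select,
    igr_score,
    rank_features,
)
from .ensemble import (
    EnsembleModel,
    MetricsReport,
    RatioSweepResult,
    RFParams,
    compute_metrics,
    cv_evaluator,
    make_undersampled_subsets,
    predict_vote,
    ratio_sweep,
    stratified_cv,
    train_ensemble,
)
from .synth import SynthConfig, generate_dataset, generate_records

__version__ = "0.1.0"
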