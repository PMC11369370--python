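"""Diffuse reflectance spectroscopy tissue classification.

Calibrates and stitches two-spectrometer DRS measurements onto a canonical
400-1600 nm grid, SNV-normalizes them, derives landmark/slope features from
class mean spectra, ranks them with ReliefF, and evaluates a linear SVM
under repeated patient-wise splits — plus a synthetic cohort generator with
known ground truth for end-to-end testing.
"""

from .classification_eval import (
    EvaluationReport,
    IterationResult,
    LinearModel,
    SplitPlan,
    evaluate,
    patient_split,
    run_iteration,
    run_repeated,
    train_classifier,
)
from .cli import PipelineConfig, run_pipeline, summarize_dataset
from .feature_extraction import (
    FeatureSpec,
    FeatureTable,
    Landmark,
    SlopePair,
    build_feature_spec,
    compute_features,
    detect_landmarks,
    propose_slope_pairs,
)
from .feature_selection import RankedFeatures, relieff_rank, select_top_k
from .preprocessing import ClassProfile, class_profiles, snv, snv_normalize, snv_normalize_set
from .spectra_io import (
    Measurement,
    RawSpectrum,
    ReferencePair,
    SpectraSet,
    Spectrum,
    WavelengthGrid,
    calibrate_reflectance,
    read_spectra_table,
    resample_to_grid,
    stitch_spectra,
    write_spectra_table,
)
from .synthetic import (
    ChromophoreSet,
    ForwardModel,
    GeneratorConfig,
    TissueComposition,
    absorption_spectrum,
    generate_dataset,
    reflectance_forward,
)

__version__ = "0.1.0"
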