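"""segqa: per-slice quality assurance for automatic contour segmentation.

Predicts the quality of auto-segmented contours — either a three-level
class (good / medium / bad, defined by per-slice Dice bins) or a
discretized Dice value — from the CT slice, the segmentation probability
map and the derived uncertainty map, without access to ground truth at
inference time.  Ships a synthetic phantom + contour-perturbation
generator with exactly controllable per-slice Dice, the full image
standardization chain, a trainable CNN classifier, and one-vs-rest
evaluation metrics.
"""

from . import metrics, model, phantom, preprocess, qa
from .metrics import (
    auc_ovr,
    balanced_accuracy,
    dsc_value_report,
    f_score,
    levels_report,
    mae,
    misclassification_histogram,
    ovr_confusion,
)
from .model import (
    ClassifierConfig,
    TrainedQAModel,
    augment,
    build_model,
    oversample_minority,
    predict,
    prepare_inputs,
    train,
)
from .phantom import (
    CalibrationError,
    PerturbationConfig,
    PhantomParams,
    SyntheticDataset,
    calibrate_to_dsc,
    generate_dataset,
    make_phantom,
    perturb_segmentation,
)
from .preprocess import (
    downsample_for_qa,
    enhance_contrast,
    normalize_size,
    resample_isotropic,
)
from .qa import (
    SliceRecord,
    assemble_channels,
    bin_quality,
    discretize_dsc,
    slice_dsc,
    threshold_probability,
    uncertainty_map,
    undiscretize_dsc,
)

__version__ = "0.1.0"
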