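"""Movelet-based activity classification from smartphone sensor streams.

Per-subject dictionaries of one-second sensor windows ("movelets") are built
from a few seconds of labeled training data, incoming accelerometer or
gyroscope data are labeled by nearest-movelet matching and a per-timepoint
majority vote, and a logistic model of prediction correctness on the
majority-vote proportion flags predictions that are likely wrong.
"""

from .io import (
    FormatError,
    InsufficientDataError,
    LabelInterval,
    LabelTrack,
    MissingActivityError,
    MoveletsError,
    SensorStream,
    ValidationError,
    label_at,
    read_classification,
    read_labels,
    read_stream,
    write_classification,
    write_labels,
    write_stream,
)
from .transforms import (
    ALL_ORIENTATIONS,
    Movelet,
    Orientation,
    REFERENCE_ORIENTATION,
    extract_movelets,
    magnitude,
    orientation_signs,
    reorient,
    window_samples,
)
from .dictionary import (
    DEFAULT_ACTIVITIES,
    Dictionary,
    build_dictionary,
    load_dictionary,
    save_dictionary,
    select_training_segment,
)
from .classifier import (
    Classification,
    MatchConfig,
    MoveletMatch,
    classify,
    dist_l2,
    match_movelet,
    sim_corr,
)
from .uncertainty import (
    CorrectnessSeries,
    DEFAULT_GRID,
    UQModel,
    apply_threshold,
    apply_uq,
    correctness_series,
    exclusion_rates,
    exclusion_roc,
    fit_uq,
    predict_correct_prob,
    threshold_sweep,
)
from .evaluation import (
    filtered_evaluation,
    plot_setting_grid,
    prediction_distribution,
    sensitivity_table,
    setting_grid,
)
from .synthetic import (
    ActivitySignature,
    ProtocolSpec,
    Segment,
    SensorBundle,
    StudyFixture,
    Wave,
    default_signatures,
    gen_stream,
    gen_study_fixture,
    scaled_walk,
)

__version__ = "0.1.0"

#: Data points per subject per month of continuous collection: two tri-axial
#: sensors sampling at rate_h for days*86400 seconds (155,520,000 for two
#: sensors at 10 Hz over a 30-day month).
def monthly_sample_count(
    n_sensors: int = 2, n_axes: int = 3, rate_h: float = 10.0, days: int = 30
) -> int:
    return int(n_sensors * n_axes * rate_h * 86400 * days)
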