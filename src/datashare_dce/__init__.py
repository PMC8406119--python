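"""datashare_dce: discrete choice experiment pipeline for health-data-sharing
preferences — efficient designs, synthetic choice data, binary and latent
class logit estimation, and acceptance-uptake prediction."""

__version__ = "0.1.0"

from .domain import (  # noqa: F401
    AttributeSpec,
    ConfigurationError,
    PriorSpec,
    StudyConfig,
    effect_code,
    effect_code_frame,
    decode_vector,
    reference_level_estimate,
    validate_dataset,
)
from .design import (  # noqa: F401
    Design,
    DesignScore,
    IdentificationError,
    bayesian_d_error,
    block_design,
    d_error,
    enumerate_profiles,
    mnl_information_matrix,
    optimize_design,
)
from .simulate import (  # noqa: F401
    TruePreferenceModel,
    simulate_choices,
    simulate_population,
    simulate_study,
)
from .screening import ScreeningReport, apply_exclusions, score_ehl  # noqa: F401
from .mnl import (  # noqa: F401
    MnlEstimate,
    SeparationError,
    country_stratified_fits,
    fit_binary_logit,
    log_likelihood,
)
from .latent_class import (  # noqa: F401
    LatentClassEstimate,
    fit_latent_class,
    select_n_classes,
)
from .postestimation import (  # noqa: F401
    acceptance_uptake,
    class_adjusted_uptake,
    extreme_profiles,
    relative_importance,
    scenario_utility,
    swait_louviere_test,
    uptake_grid,
)
from .reporting import PipelineResult, RunManifest, render_tables, run_pipeline  # noqa: F401
from . import defaults  # noqa: F401
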