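import numpy as np
import pytest
from hypothesis import settings

from datashare_dce import TruePreferenceModel, defaults, simulate_study
from datashare_dce.domain import AttributeSpec, StudyConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """The final study configuration (5 attributes, K=13, 32 tasks / 4 blocks)."""
    return defaults.study_config()


@pytest.fixture(scope="session")
def toy_config():
    """One binary attribute: K=1, the smallest identifiable study."""
    return StudyConfig(
        attributes=(AttributeSpec("a", ("x", "y"), "y"),),
        info_types=("only",),
        n_blocks=1,
        tasks_per_block=2,
    )


@pytest.fixture(scope="session")
def pooled_source():
    """Pooled reference estimates as a plain coefficient source."""
    return {
        "beta": defaults.POOLED_LOGIT["beta"].copy(),
        "asc": defaults.POOLED_LOGIT["asc"],
    }


@pytest.fixture(scope="session")
def single_class_model():
    """Single-class generating truth at the pooled reference estimates."""
    return TruePreferenceModel(
        class_betas=defaults.POOLED_LOGIT["beta"][None, :],
        class_asc=np.array([defaults.POOLED_LOGIT["asc"]]),
        membership_coefs=np.zeros((0, 4)),
    )


@pytest.fixture(scope="session")
def four_class_model():
    return defaults.four_class_model()


@pytest.fixture(scope="session")
def small_study(config, four_class_model):
    """A 300-respondent synthetic study without attrition (reused read-only)."""
    return simulate_study(
        config, four_class_model, n=300, seed=42,
        speeder_fraction=0.0, incomplete_fraction=0.0,
    )
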