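"""Default study configuration and reference parameter sets.

The package ships the configuration of a four-country (Sweden, Norway,
Iceland, United Kingdom) survey on public willingness to share health data:
five attributes describing a hypothetical data-sharing situation, a
32-task / 4-block design, and 16 accept/reject tasks per respondent
(8 per information type).

Two published coefficient sets are bundled as reference inputs:

* :data:`POOLED_LOGIT` -- the pooled binary logit estimates over all four
  countries (13 effect-coded level estimates plus an acceptance-side
  intercept), used for worked uptake examples and as a single-class
  generating model.
* :data:`FOUR_CLASS_MODEL` -- a four-class latent class model with a
  country-driven class-membership model; the default generating truth for
  the synthetic-data module.

Conventions: the intercept enters the *acceptance* utility, so
P(accept) = logistic(intercept + beta' x). Class-membership coefficients are
relative to the last class; country coefficients are relative to the
United Kingdom.
"""

from __future__ import annotations

import numpy as np

from .domain import AttributeSpec, StudyConfig

__all__ = [
    "study_config",
    "COUNTRIES",
    "COUNTRY_SHARES",
    "POOLED_LOGIT",
    "POOLED_LOGIT_SE",
    "FOUR_CLASS_MODEL",
    "AVERAGE_CLASS_PROBABILITIES",
    "PUBLISHED_UPTAKE_GRID",
    "ATTRITION",
    "EHL_ITEM_PROBS",
]

# Attribute and level vocabulary; the reference level is listed last and is
# the one reported as "(Ref)" in the fitted tables.
_ATTRIBUTES = (
    AttributeSpec(
        "collector",
        ("tech_company", "research_project", "healthcare_provider"),
        "healthcare_provider",
    ),
    AttributeSpec(
        "new_user",
        ("tech_company", "pharma_company", "research_project", "national_authority"),
        "national_authority",
    ),
    AttributeSpec(
        "reason",
        ("develop_product", "marketing", "policy_initiative", "evaluate_quality"),
        "evaluate_quality",
    ),
    AttributeSpec(
        "information",
        ("not_informed", "informed", "opt_out", "consent"),
        "consent",
    ),
    AttributeSpec(
        "review",
        ("no_review", "review_sharing", "review_sharing_use"),
        "review_sharing_use",
    ),
)


def study_config(seed: int = 0) -> StudyConfig:
    """The final study configuration: 5 attributes (3/4/4/4/3 levels, K=13),
    two information types, 32 tasks in 4 blocks of 8."""
    return StudyConfig(
        attributes=_ATTRIBUTES,
        info_types=("genetic", "lifestyle"),
        n_blocks=4,
        tasks_per_block=8,
        seed=seed,
    )


def pilot_config(seed: int = 0) -> StudyConfig:
    """The pilot configuration: the information attribute had 3 levels
    (the opt-out level was added afterwards) and 28 tasks in 4 blocks of 7."""
    attrs = list(_ATTRIBUTES)
    attrs[3] = AttributeSpec(
        "information", ("not_informed", "informed", "consent"), "consent"
    )
    return StudyConfig(
        attributes=tuple(attrs),
        info_types=("genetic", "lifestyle"),
        n_blocks=4,
        tasks_per_block=7,
        seed=seed,
    )


COUNTRIES = ("sweden", "norway", "uk", "iceland")

# Retained-sample country proportions (481 / 465 / 477 / 544 of 1967).
COUNTRY_SHARES = {
    "sweden": 481 / 1967,
    "norway": 465 / 1967,
    "uk": 477 / 1967,
    "iceland": 544 / 1967,
}

# Pooled binary logit estimates, canonical coding order:
# collector[tech_company, research_project], new_user[tech_company,
# pharma_company, research_project], reason[develop_product, marketing,
# policy_initiative], information[not_informed, informed, opt_out],
# review[no_review, review_sharing].
POOLED_LOGIT = {
    "beta": np.array(
        [
            -0.19, 0.08,
            -0.26, -0.03, 0.12,
            0.15, -0.47, 0.11,
            -0.90, -0.08, 0.51,
            -0.52, 0.25,
        ]
    ),
    "asc": 0.51,
}

POOLED_LOGIT_SE = {
    "beta": np.full(13, 0.02),
    "asc": 0.01,
}

# Four-class generating model. Rows follow the canonical coding order above.
_CLASS_BETAS = np.array(
    [
        # class 1
        [-0.26, 0.14, -0.41, -0.12, 0.17, 0.56, -1.06, 0.10,
         -1.47, 0.02, 0.82, -0.78, 0.43],
        # class 2
        [-0.37, 0.15, -0.53, -0.08, 0.29, 0.33, -0.98, 0.25,
         -0.66, -0.04, 0.35, -1.07, 0.50],
        # class 3
        [-0.36, 0.21, -0.07, -0.08, 0.07, 0.04, -0.41, 0.05,
         -2.95, -0.41, 1.61, -0.58, 0.28],
        # class 4
        [-0.40, 0.16, -0.59, -0.05, 0.23, 0.43, -0.76, -0.05,
         -1.36, -0.11, 0.84, -0.75, 0.46],
    ]
)

_CLASS_ASC = np.array([3.60, 0.31, 0.84, -2.01])

# Class-membership multinomial logit, reference = class 4.
# Columns: constant, sweden, norway, iceland (UK is the reference country).
_MEMBERSHIP = np.array(
    [
        [0.96, -0.29, -1.06, -0.76],
        [0.73, 0.09, -0.78, 0.15],
        [0.87, -0.91, -0.50, -0.98],
    ]
)

AVERAGE_CLASS_PROBABILITIES = np.array([0.27, 0.32, 0.23, 0.18])

# Published class-adjusted acceptance-uptake grid (percent) for scenarios
# sharing from a health care provider to a technological company.
# Rows: (review level, reason level); columns: information level.
PUBLISHED_UPTAKE_GRID = {
    ("no_review", "develop_product"): (32, 49, 63, 63),
    ("no_review", "marketing"): (18, 37, 53, 60),
    ("no_review", "policy_initiative"): (29, 47, 61, 61),
    ("no_review", "evaluate_quality"): (32, 51, 64, 64),
    ("review_sharing", "develop_product"): (45, 65, 77, 76),
    ("review_sharing", "marketing"): (32, 52, 65, 65),
    ("review_sharing", "policy_initiative"): (43, 63, 75, 74),
    ("review_sharing", "evaluate_quality"): (46, 66, 77, 76),
    ("review_sharing_use", "develop_product"): (45, 65, 77, 76),
    ("review_sharing_use", "marketing"): (31, 53, 65, 64),
    ("review_sharing_use", "policy_initiative"): (43, 63, 74, 73),
    ("review_sharing_use", "evaluate_quality"): (46, 66, 77, 76),
}
UPTAKE_GRID_INFO_ORDER = ("not_informed", "informed", "opt_out", "consent")

# Survey attrition reference: 5,199 questionnaires received, 97 removed for
# completing in under 5 minutes, 3,135 for not completing, 1,967 retained.
ATTRITION = {
    "n_received": 5199,
    "n_speeders": 97,
    "n_incomplete": 3135,
    "n_retained": 1967,
    "speeder_fraction": 0.02,
    "incomplete_fraction": 0.60,
}

# Per-item response probabilities for the 8 eHealth-literacy items
# (strongly disagree, disagree, neither, agree, strongly agree), chosen so
# independent items yield roughly 30% inadequate / 43% problematic /
# 27% sufficient literacy, matching the surveyed populations.
EHL_ITEM_PROBS = (0.015, 0.029, 0.107, 0.550, 0.299)


def four_class_model():
    """Default four-class generating truth (lazy import avoids a cycle)."""
    from .simulate import TruePreferenceModel

    return TruePreferenceModel(
        class_betas=_CLASS_BETAS.copy(),
        class_asc=_CLASS_ASC.copy(),
        membership_coefs=_MEMBERSHIP.copy(),
        countries=COUNTRIES,
    )


FOUR_CLASS_MODEL = four_class_model
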