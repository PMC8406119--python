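import numpy as np
import pandas as pd
import pytest

from datashare_dce import (
    acceptance_uptake,
    class_adjusted_uptake,
    defaults,
    effect_code,
    enumerate_profiles,
    extreme_profiles,
    fit_latent_class,
    relative_importance,
    scenario_utility,
    simulate_study,
    swait_louviere_test,
    uptake_grid,
)
from datashare_dce.domain import AttributeSpec, StudyConfig
from datashare_dce.latent_class import LatentClassEstimate


def published_lc(config) -> LatentClassEstimate:
    """Reference four-class estimates wrapped as a fitted-model object."""
    model = defaults.four_class_model()
    return LatentClassEstimate(
        n_classes=4,
        class_betas=model.class_betas,
        class_asc=model.class_asc,
        membership_coefs=model.membership_coefs,
        membership_countries=("sweden", "norway", "iceland"),
        average_class_probability=defaults.AVERAGE_CLASS_PROBABILITIES.copy(),
        posterior=np.zeros((0, 4)),
        respondent_ids=np.zeros(0),
        log_likelihood=-14797.0,
        aic=29730.0,
        bic=float("nan"),
        n_parameters=68,
        n_obs=31472,
        converged=True,
        config=config,
    )


class TestRelativeImportance:
    def test_pooled_reference_values(self, config, pooled_source):
        table = relative_importance(pooled_source, config).set_index("attribute")
        # information spans 0.51 - (-0.90) = 1.41 and dominates
        assert table.loc["information", "range"] == pytest.approx(1.41)
        assert table.loc["information", "importance"] == pytest.approx(1.0)
        assert table.loc["review", "importance"] == pytest.approx(0.79 / 1.41,
                                                                  abs=1e-9)
        assert table.index[0] == "information"

    def test_single_attribute_importance_is_one(self):
        cfg = StudyConfig(
            attributes=(AttributeSpec("a", ("x", "y"), "y"),),
            n_blocks=1, tasks_per_block=1,
        )
        table = relative_importance({"beta": [0.4], "asc": 0.0}, cfg)
        assert table["importance"].tolist() == [1.0]

    def test_equal_ranges_all_score_one(self):
        cfg = StudyConfig(
            attributes=(
                AttributeSpec("a", ("x", "y"), "y"),
                AttributeSpec("b", ("u", "v"), "v"),
            ),
            n_blocks=1, tasks_per_block=1,
        )
        table = relative_importance({"beta": [0.3, 0.3], "asc": 0.0}, cfg)
        assert table["importance"].tolist() == [1.0, 1.0]


class TestScenarioUtility:
    def test_most_preferred_scenario_sums_to_1_78(self, config, pooled_source):
        best = {
            "collector": "healthcare_provider",
            "new_user": "national_authority",
            "reason": "evaluate_quality",
            "information": "opt_out",
            "review": "review_sharing_use",
        }
        # 0.11 + 0.17 + 0.21 + 0.51 + 0.27 + 0.51 (constant)
        assert scenario_utility(best, pooled_source, config) == pytest.approx(1.78)

    def test_all_zero_coefficients_return_constant(self, config):
        src = {"beta": np.zeros(13), "asc": 0.73}
        scenario = {a.name: a.levels[0] for a in config.attributes}
        assert scenario_utility(scenario, src, config) == pytest.approx(0.73)

    def test_additivity_in_single_level_changes(self, config, pooled_source):
        base = {a.name: a.levels[0] for a in config.attributes}
        v0 = scenario_utility(base, pooled_source, config)
        changed = dict(base, reason="marketing")
        v1 = scenario_utility(changed, pooled_source, config)
        # develop_product 0.15 -> marketing -0.47
        assert v1 - v0 == pytest.approx(-0.47 - 0.15)


class TestAcceptanceUptake:
    def test_zero_utility_is_half(self):
        assert acceptance_uptake(0.0) == 0.5

    def test_least_preferred_scenario_is_14_percent(self, config, pooled_source):
        worst = {
            "collector": "tech_company",
            "new_user": "tech_company",
            "reason": "marketing",
            "information": "not_informed",
            "review": "no_review",
        }
        v = scenario_utility(worst, pooled_source, config)
        assert v == pytest.approx(-1.83)
        assert acceptance_uptake(v) == pytest.approx(0.138, abs=0.001)

    def test_logistic_symmetry(self):
        for v in (-2.3, -0.5, 0.0, 1.7):
            assert acceptance_uptake(v) + acceptance_uptake(-v) == pytest.approx(1.0)


class TestClassAdjustedUptake:
    def test_single_class_equals_plain_uptake(self, config, small_study):
        _, choices, _ = small_study
        lc = fit_latent_class(choices, config, 1, seed=0)
        scenario = {a.name: a.levels[0] for a in config.attributes}
        assert class_adjusted_uptake(scenario, lc, config) == pytest.approx(
            acceptance_uptake(scenario_utility(scenario, lc, config, cls=0))
        )

    def test_degenerate_weights_pick_one_class(self, config):
        lc = published_lc(config)
        scenario = {
            "collector": "healthcare_provider",
            "new_user": "tech_company",
            "reason": "develop_product",
            "information": "not_informed",
            "review": "no_review",
        }
        w = np.array([1.0, 0.0, 0.0, 0.0])
        assert class_adjusted_uptake(scenario, lc, config, weights=w) == pytest.approx(
            acceptance_uptake(scenario_utility(scenario, lc, config, cls=0))
        )

    def test_reference_scenario_near_published_31_percent(self, config):
        # share to a tech company for product development, no information,
        # no review: four hand-weighted class logistics give ~0.31
        lc = published_lc(config)
        scenario = {
            "collector": "healthcare_provider",
            "new_user": "tech_company",
            "reason": "develop_product",
            "information": "not_informed",
            "review": "no_review",
        }
        assert class_adjusted_uptake(scenario, lc, config) == pytest.approx(
            0.31, abs=0.01
        )

    def test_weights_must_sum_to_one(self, config):
        lc = published_lc(config)
        scenario = {a.name: a.levels[0] for a in config.attributes}
        with pytest.raises(ValueError):
            class_adjusted_uptake(scenario, lc, config, weights=np.full(4, 0.3))


class TestUptakeGrid:
    def test_grid_covers_48_cells(self, config):
        lc = published_lc(config)
        grid = uptake_grid(lc, config, "healthcare_provider", "tech_company")
        assert len(grid) == 12  # 3 review x 4 reason rows
        info_cols = [c for c in grid.columns if c not in ("review", "reason")]
        assert len(info_cols) == 4
        cells = grid[info_cols].to_numpy()
        assert cells.size == 48
        assert np.all((cells > 0) & (cells < 100))

    def test_opt_out_dominates_not_informed(self, config):
        # every class prefers opt-out to not-informed, so each grid row must
        lc = published_lc(config)
        grid = uptake_grid(lc, config, "healthcare_provider", "tech_company")
        assert np.all(grid["opt_out"].to_numpy() >= grid["not_informed"].to_numpy())

    def test_raising_a_level_coefficient_raises_its_uptake(self, config):
        lc = published_lc(config)
        scenario = {
            "collector": "healthcare_provider",
            "new_user": "tech_company",
            "reason": "develop_product",
            "information": "informed",
            "review": "no_review",
        }
        before = class_adjusted_uptake(scenario, lc, config)
        bumped = published_lc(config)
        cols = config.column_names()
        bumped.class_betas = bumped.class_betas.copy()
        bumped.class_betas[:, cols.index("information[informed]")] += 0.2
        after = class_adjusted_uptake(scenario, bumped, config)
        assert after > before


class TestExtremeProfiles:
    def test_brute_force_agreement_over_all_576_profiles(self, config, pooled_source):
        best, worst = extreme_profiles(pooled_source, config)
        utils = {
            tuple(p.values()): scenario_utility(p, pooled_source, config)
            for p in enumerate_profiles(config)
        }
        assert max(utils, key=utils.get) == tuple(best.values())
        assert min(utils, key=utils.get) == tuple(worst.values())
        assert best == {
            "collector": "healthcare_provider",
            "new_user": "national_authority",
            "reason": "evaluate_quality",
            "information": "opt_out",
            "review": "review_sharing_use",
        }
        assert worst == {
            "collector": "tech_company",
            "new_user": "tech_company",
            "reason": "marketing",
            "information": "not_informed",
            "review": "no_review",
        }


class TestSwaitLouviere:
    def test_identical_samples_recover_unit_scale(self, config, single_class_model):
        _, choices, _ = simulate_study(
            config, single_class_model, n=250, seed=51,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        res = swait_louviere_test(choices, choices.copy(), config)
        assert res.lambda_hat == pytest.approx(1.0, abs=0.01)
        assert res.p_value > 0.99
        assert res.df == config.k + 1

    def test_doubled_utilities_recover_lambda_two(self, config, pooled_source):
        from datashare_dce import TruePreferenceModel

        base = TruePreferenceModel(
            class_betas=pooled_source["beta"][None, :],
            class_asc=np.array([pooled_source["asc"]]),
            membership_coefs=np.zeros((0, 4)),
        )
        doubled = TruePreferenceModel(
            class_betas=2 * pooled_source["beta"][None, :],
            class_asc=np.array([2 * pooled_source["asc"]]),
            membership_coefs=np.zeros((0, 4)),
        )
        _, a, _ = simulate_study(config, base, n=500, seed=52,
                                 speeder_fraction=0.0, incomplete_fraction=0.0)
        _, b, _ = simulate_study(config, doubled, n=500, seed=53,
                                 speeder_fraction=0.0, incomplete_fraction=0.0)
        res = swait_louviere_test(a, b, config)
        assert res.lambda_hat == pytest.approx(2.0, rel=0.2)

    def test_constant_level_usage_is_unidentified(self, config, single_class_model):
        _, choices, _ = simulate_study(
            config, single_class_model, n=100, seed=54,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        frozen = choices.copy()
        frozen["information"] = "consent"
        with pytest.raises(ValueError, match="identif"):
            swait_louviere_test(choices, frozen, config)
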