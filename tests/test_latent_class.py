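import itertools
import math

import numpy as np
import pandas as pd
import pytest

from datashare_dce import (
    TruePreferenceModel,
    fit_binary_logit,
    fit_latent_class,
    select_n_classes,
    simulate_study,
)
from datashare_dce.domain import AttributeSpec, StudyConfig
from datashare_dce.latent_class import (
    LCParams,
    e_step,
    m_step,
    n_parameters,
    observed_loglik,
    prepare,
)


@pytest.fixture(scope="module")
def tiny_config():
    """Two binary attributes: K=2, smallest config with >1 coded column."""
    return StudyConfig(
        attributes=(
            AttributeSpec("a", ("x", "y"), "y"),
            AttributeSpec("b", ("u", "v"), "v"),
        ),
        info_types=("only",),
        n_blocks=1,
        tasks_per_block=4,  # full factorial: identifies asc + 2 betas per class
    )


def tiny_dataset(tiny_config, choices, countries=None):
    """n respondents x 2 tasks over the two binary attributes."""
    tasks = [{"a": "x", "b": "u"}, {"a": "y", "b": "v"}]
    rows = []
    for r, resp_choices in enumerate(choices):
        for t, ch in enumerate(resp_choices):
            rows.append({
                "respondent_id": r + 1,
                "country": (countries or ["uk"] * len(choices))[r],
                "info_type": "only", "block": 1, "task_id": t + 1,
                "choice": ch, **tasks[t],
            })
    return pd.DataFrame(rows)


def two_class_model(k, sep=2.0):
    """Well-separated two-class truth with uniform membership."""
    betas = np.vstack([np.full(k, 0.8), np.full(k, -0.8)])
    return TruePreferenceModel(
        class_betas=betas,
        class_asc=np.array([sep, -sep]),
        membership_coefs=np.zeros((1, 4)),
    )


class TestEStep:
    def test_single_class_posterior_is_one(self, tiny_config):
        df = tiny_dataset(tiny_config, [(1, 0), (0, 1)])
        data = prepare(df, tiny_config)
        params = LCParams(np.zeros((1, 2)), np.zeros(1), np.zeros((0, 1)))
        post, _ = e_step(params, data)
        assert post == pytest.approx(np.ones((2, 1)))

    def test_identical_classes_posterior_equals_prior(self, tiny_config):
        df = tiny_dataset(tiny_config, [(1, 0), (0, 1), (1, 1)])
        data = prepare(df, tiny_config)
        const = 0.7  # prior share e^0.7 / (1 + e^0.7) for class 1
        params = LCParams(
            np.tile(np.array([0.3, -0.2]), (2, 1)),
            np.array([0.5, 0.5]),
            np.array([[const]]),
        )
        post, _ = e_step(params, data)
        share1 = math.exp(const) / (1 + math.exp(const))
        assert post[:, 0] == pytest.approx(np.full(3, share1))

    def test_matches_brute_force_mixture_likelihood(self, tiny_config):
        # 2 respondents x 2 tasks, C=2: enumerate the joint probabilities
        df = tiny_dataset(tiny_config, [(1, 0), (0, 1)])
        data = prepare(df, tiny_config)
        params = LCParams(
            np.array([[0.4, -0.9], [-1.1, 0.2]]),
            np.array([0.3, -0.6]),
            np.array([[0.25]]),
        )
        pi1 = math.exp(0.25) / (1 + math.exp(0.25))
        tasks_coded = [np.array([1.0, 1.0]), np.array([-1.0, -1.0])]
        y = [(1, 0), (0, 1)]
        expected = 0.0
        for r in range(2):
            lik = 0.0
            for c, w in ((0, pi1), (1, 1 - pi1)):
                pr = w
                for t in range(2):
                    v = params.class_asc[c] + float(
                        params.class_betas[c] @ tasks_coded[t]
                    )
                    p = 1 / (1 + math.exp(-v))
                    pr *= p if y[r][t] == 1 else 1 - p
                lik += pr
            expected += math.log(lik)
        assert observed_loglik(params, data) == pytest.approx(expected)


class TestMStep:
    def test_full_mass_on_one_class_reproduces_pooled_fit(self, config, small_study):
        _, choices, _ = small_study
        data = prepare(choices, config)
        posterior = np.column_stack(
            [np.ones(data.n_resp), np.zeros(data.n_resp)]
        )
        prev = LCParams(np.zeros((2, config.k)), np.zeros(2), np.zeros((1, 4)))
        params = m_step(posterior, data, prev)
        pooled = fit_binary_logit(choices, config)
        assert params.class_betas[0] == pytest.approx(pooled.beta, abs=1e-6)
        assert params.class_asc[0] == pytest.approx(pooled.asc, abs=1e-6)

    def test_uniform_posterior_keeps_classes_identical(self, tiny_config):
        df = tiny_dataset(tiny_config, [(1, 0), (0, 1), (1, 1), (0, 0)])
        data = prepare(df, tiny_config)
        posterior = np.full((4, 2), 0.5)
        prev = LCParams(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 1)))
        params = m_step(posterior, data, prev)
        assert params.class_betas[0] == pytest.approx(params.class_betas[1])
        assert params.class_asc[0] == pytest.approx(params.class_asc[1])

    def test_em_iterations_never_decrease_loglik(self, tiny_config):
        # monotonicity audit across 100 random small fixtures
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_resp = int(rng.integers(6, 14))
            choices = rng.integers(0, 2, size=(n_resp, 2))
            df = tiny_dataset(tiny_config, [tuple(c) for c in choices])
            data = prepare(df, tiny_config)
            post = rng.dirichlet(np.ones(2), size=n_resp)
            params = LCParams(np.zeros((2, 2)), np.zeros(2), np.zeros((1, 1)))
            params = m_step(post, data, params)
            ll_prev = -np.inf
            for _ in range(8):
                post, ll = e_step(params, data)
                assert ll >= ll_prev - 1e-9, f"fixture {trial}"
                ll_prev = ll
                params = m_step(post, data, params)


class TestFitLatentClass:
    def test_one_class_reproduces_binary_logit(self, config, small_study):
        _, choices, _ = small_study
        lc = fit_latent_class(choices, config, n_classes=1, seed=0)
        pooled = fit_binary_logit(choices, config)
        assert lc.class_betas[0] == pytest.approx(pooled.beta, abs=1e-6)
        assert lc.class_asc[0] == pytest.approx(pooled.asc, abs=1e-6)
        assert lc.log_likelihood == pytest.approx(pooled.log_likelihood, abs=1e-6)
        assert lc.n_parameters == config.k + 1

    def test_parameter_count_for_four_classes(self):
        assert n_parameters(4, 13, 4) == 68

    def test_posterior_rows_sum_to_one(self, tiny_config):
        model = two_class_model(2)
        _, choices, _ = simulate_study(
            tiny_config, model, n=120, seed=31,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        lc = fit_latent_class(choices, tiny_config, 2, n_starts=3, seed=1)
        assert lc.posterior.sum(axis=1) == pytest.approx(np.ones(120), abs=1e-10)
        assert lc.average_class_probability == pytest.approx(
            lc.posterior.mean(axis=0)
        )
        assert lc.average_class_probability.sum() == pytest.approx(1.0)

    def test_classes_reported_in_descending_share_order(self, tiny_config):
        model = two_class_model(2)
        _, choices, _ = simulate_study(
            tiny_config, model, n=150, seed=32,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        lc = fit_latent_class(choices, tiny_config, 2, n_starts=3, seed=2)
        assert np.all(np.diff(lc.average_class_probability) <= 1e-12)
        assert lc.aic == pytest.approx(
            2 * lc.n_parameters - 2 * lc.log_likelihood
        )

    def test_different_seeds_reach_same_canonical_model(self, tiny_config):
        # label/initialization invariance on well-separated classes
        model = two_class_model(2)
        _, choices, _ = simulate_study(
            tiny_config, model, n=200, seed=33,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        a = fit_latent_class(choices, tiny_config, 2, n_starts=4, seed=11)
        b = fit_latent_class(choices, tiny_config, 2, n_starts=4, seed=99)
        assert a.class_betas == pytest.approx(b.class_betas, abs=1e-4)
        assert a.class_asc == pytest.approx(b.class_asc, abs=1e-4)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)

    def test_maximized_likelihood_matches_dense_grid_search(self, toy_config):
        # <=3 respondents, <=3 tasks, C=2: the fitted likelihood must reach
        # (within grid resolution) the best point of a brute-force sweep
        df = pd.DataFrame([
            {"respondent_id": r, "country": "uk", "info_type": "only",
             "block": 1, "task_id": t + 1, "choice": ch,
             "a": "x" if t == 0 else "y"}
            for r, resp in enumerate([(1, 0), (0, 0), (1, 1)], start=1)
            for t, ch in enumerate(resp)
        ])
        lc = fit_latent_class(df, toy_config, 2, n_starts=20, seed=3)

        x = np.array([1.0, -1.0])           # coded task profiles
        y = np.array([[1, 0], [0, 0], [1, 1]], dtype=float)
        grid = np.linspace(-3, 3, 13)
        best = -np.inf
        for b1, a1, b2, a2, m in itertools.product(grid, repeat=5):
            p1 = 1 / (1 + np.exp(-(a1 + b1 * x)))
            p2 = 1 / (1 + np.exp(-(a2 + b2 * x)))
            l1 = np.prod(np.where(y == 1, p1, 1 - p1), axis=1)
            l2 = np.prod(np.where(y == 1, p2, 1 - p2), axis=1)
            pi1 = 1 / (1 + np.exp(-m))
            ll = np.log(pi1 * l1 + (1 - pi1) * l2).sum()
            best = max(best, ll)
        assert lc.log_likelihood >= best - 1e-9
        assert lc.log_likelihood - best < 0.5  # grid resolution bound


class TestSelectNClasses:
    def test_two_class_data_selects_two_classes(self, tiny_config):
        hits = 0
        for seed in range(5):
            model = two_class_model(2)
            _, choices, _ = simulate_study(
                tiny_config, model, n=150, seed=100 + seed,
                speeder_fraction=0.0, incomplete_fraction=0.0,
            )
            table = select_n_classes(choices, tiny_config, (1, 2, 3),
                                     n_starts=4, seed=seed)
            assert table.loc[table["best"], "n_classes"].iloc[0] in (2, 3)
            if table.loc[table["best"], "n_classes"].iloc[0] == 2:
                hits += 1
        assert hits >= 4

    def test_nested_loglik_is_monotone(self, tiny_config):
        model = two_class_model(2)
        _, choices, _ = simulate_study(
            tiny_config, model, n=150, seed=41,
            speeder_fraction=0.0, incomplete_fraction=0.0,
        )
        table = select_n_classes(choices, tiny_config, (1, 2, 3),
                                 n_starts=4, seed=5)
        lls = table["log_likelihood"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-4)

    def test_single_respondent_flagged_unidentifiable(self, tiny_config):
        df = tiny_dataset(tiny_config, [(1, 0)])
        table = select_n_classes(df, tiny_config, (1, 2), n_starts=2, seed=0)
        assert table.loc[table["n_classes"] == 2, "error"].notna().all()
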