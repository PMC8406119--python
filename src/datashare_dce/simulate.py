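"""Synthetic survey populations and choice data.

The generator emulates the structure of the four-country survey: roughly
2,000 retained respondents drawn from Sweden, Norway, the United Kingdom
and Iceland; four latent preference classes whose membership probabilities
follow a country-driven multinomial logit; 16 binary accept/reject tasks
per respondent (8 per information type, drawn from the respondent's design
block); 8 five-category eHealth-literacy items; and screening fields
(survey duration, completion flag) so the exclusion filters have work to do.

Choice behaviour is class-conditional binary logit:
P(accept) = logistic(asc_c + beta_c' x) with x the effect-coded profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from . import defaults
from .design import Design, block_design, random_design
from .domain import StudyConfig, effect_code_frame

__all__ = [
    "TruePreferenceModel",
    "simulate_population",
    "simulate_choices",
    "simulate_study",
    "default_design",
]

EHL_CATEGORIES = (
    "strongly_disagree",
    "disagree",
    "neither",
    "agree",
    "strongly_agree",
)

GENDERS = ("female", "male", "other")
GENDER_PROBS = (0.513, 0.482, 0.005)


@dataclass
class TruePreferenceModel:
    """Generating truth: per-class utilities plus a class-membership model.

    Parameters
    ----------
    class_betas : (C, K) array
        Effect-coded level coefficients per latent class.
    class_asc : (C,) array
        Per-class acceptance constant (added to the acceptance utility).
    membership_coefs : (C-1, 1 + n_countries - 1) array
        Multinomial-logit coefficients of class membership relative to the
        last class: a constant plus one coefficient per non-reference
        country. The reference country is the last entry of ``countries``
        minus ... the country *not* given a column (United Kingdom by
        default).
    countries : tuple of str
        Country labels; columns of the membership model correspond to all
        countries except the reference one, in this order with the
        reference (``uk``) skipped.
    """

    class_betas: np.ndarray
    class_asc: np.ndarray
    membership_coefs: np.ndarray
    countries: tuple[str, ...] = defaults.COUNTRIES
    reference_country: str = "uk"

    def __post_init__(self) -> None:
        self.class_betas = np.atleast_2d(np.asarray(self.class_betas, dtype=float))
        self.class_asc = np.asarray(self.class_asc, dtype=float)
        self.membership_coefs = np.asarray(self.membership_coefs, dtype=float)
        c = self.n_classes
        if self.class_asc.shape != (c,):
            raise ValueError("class_asc must have one entry per class")
        if c > 1:
            expected = (c - 1, 1 + len(self.countries) - 1)
            if self.membership_coefs.shape != expected:
                raise ValueError(
                    f"membership_coefs must have shape {expected}, "
                    f"got {self.membership_coefs.shape}"
                )

    @property
    def n_classes(self) -> int:
        return self.class_betas.shape[0]

    @property
    def k(self) -> int:
        return self.class_betas.shape[1]

    def membership_countries(self) -> tuple[str, ...]:
        return tuple(c for c in self.countries if c != self.reference_country)

    def class_shares(self, country: str) -> np.ndarray:
        """Softmax class-membership probabilities for one country."""
        if self.n_classes == 1:
            return np.array([1.0])
        cols = self.membership_countries()
        x = np.zeros(1 + len(cols))
        x[0] = 1.0
        if country != self.reference_country:
            x[1 + cols.index(country)] = 1.0
        logits = np.append(self.membership_coefs @ x, 0.0)  # reference class last
        return softmax(logits)

    def accept_probability(self, coded: np.ndarray, cls: int) -> np.ndarray:
        return expit(self.class_asc[cls] + coded @ self.class_betas[cls])


def _truncated_normal_ages(n: int, rng: np.random.Generator) -> np.ndarray:
    ages = rng.normal(49.0, 16.8, size=n)
    while True:
        bad = (ages < 18) | (ages > 90)
        if not bad.any():
            return np.round(ages).astype(int)
        ages[bad] = rng.normal(49.0, 16.8, size=int(bad.sum()))


def simulate_population(
    n: int,
    country_shares: dict[str, float] | None = None,
    model: TruePreferenceModel | None = None,
    seed: int = 0,
    config: StudyConfig | None = None,
    speeder_fraction: float = defaults.ATTRITION["speeder_fraction"],
    incomplete_fraction: float = defaults.ATTRITION["incomplete_fraction"],
    ehl_item_probs: tuple[float, ...] = defaults.EHL_ITEM_PROBS,
    min_duration: float = 5.0,
) -> pd.DataFrame:
    """Draw a synthetic respondent table with latent class labels.

    Countries are drawn from ``country_shares``; each respondent's latent
    class from the model's country-conditional membership softmax. Ages,
    genders and eHealth-literacy items are drawn independently of class.
    Screening fields are drawn so that on average ``speeder_fraction`` of
    respondents finish in under ``min_duration`` minutes and
    ``incomplete_fraction`` (disjointly) fail to complete.

    Returns a DataFrame with one row per respondent including the latent
    ``true_class`` (1-based) — downstream consumers must not peek at it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model is None:
        model = defaults.four_class_model()
    if config is None:
        config = defaults.study_config()
    if country_shares is None:
        country_shares = defaults.COUNTRY_SHARES
    shares = np.array([country_shares[c] for c in model.countries])
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError("country shares must sum to 1")
    if speeder_fraction + incomplete_fraction > 1:
        raise ValueError("attrition fractions exceed 1")

    rng = np.random.default_rng(seed)
    country_idx = rng.choice(len(model.countries), size=n, p=shares)
    countries = np.array(model.countries)[country_idx]

    class_probs = np.array([model.class_shares(c) for c in model.countries])
    u = rng.random(n)
    cum = np.cumsum(class_probs[country_idx], axis=1)
    true_class = (u[:, None] > cum).sum(axis=1) + 1  # 1-based

    # screening category: speeder / incomplete / retained, drawn disjointly
    cat = rng.choice(
        3, size=n, p=[speeder_fraction, incomplete_fraction,
                      1 - speeder_fraction - incomplete_fraction]
    )
    duration = np.exp(rng.normal(np.log(14.0), 0.45, size=n)) + min_duration
    duration[cat == 0] = rng.uniform(0.5, min_duration - 1e-6, size=int((cat == 0).sum()))
    completed = cat != 1

    ehl = rng.choice(5, size=(n, 8), p=np.asarray(ehl_item_probs))
    data = {
        "respondent_id": np.arange(1, n + 1),
        "country": countries,
        "age": _truncated_normal_ages(n, rng),
        "gender": rng.choice(GENDERS, size=n, p=GENDER_PROBS),
        "duration_minutes": np.round(duration, 2),
        "completed": completed,
        "true_class": true_class,
    }
    for j in range(8):
        data[f"ehl_{j + 1}"] = np.array(EHL_CATEGORIES)[ehl[:, j]]
    for info in config.info_types:
        data[f"block_{info}"] = rng.integers(1, config.n_blocks + 1, size=n)
    return pd.DataFrame(data)


def default_design(config: StudyConfig, seed: int = 0) -> Design:
    """A seeded, blocked design used when none is supplied.

    A random distinct-task draw (redrawn until all K+1 parameters are
    identified) followed by greedy blocking; adequate for simulation
    fixtures (design optimization is a separate, explicit step).
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        d = random_design(config, config.n_tasks, rng)
        frame = pd.DataFrame(d.tasks)
        X = effect_code_frame(frame, config)
        Xa = np.column_stack([X, np.ones(len(frame))])
        if np.linalg.matrix_rank(Xa) == config.k + 1:
            return block_design(d, config.n_blocks, config, seed=seed)
    raise RuntimeError("could not draw an identified design")  # pragma: no cover


def simulate_choices(
    population: pd.DataFrame,
    design: Design,
    model: TruePreferenceModel,
    config: StudyConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate accept/reject answers for every respondent and info type.

    Each respondent answers the tasks of their assigned block once per
    information type; acceptance is Bernoulli with the class-conditional
    logit probability. Returns the long-format choice table.
    """
    rng = np.random.default_rng(seed)
    frame = design.to_frame(config)
    blocks = {
        b: frame[frame["block"] == b].reset_index(drop=True)
        for b in sorted(frame["block"].unique())
    }
    pieces = []
    for info in config.info_types:
        bcol = f"block_{info}"
        if bcol not in population.columns:
            raise ValueError(f"population missing block assignment column {bcol!r}")
        for b, tasks in blocks.items():
            resp = population[population[bcol] == b]
            if resp.empty:
                continue
            n_r, n_t = len(resp), len(tasks)
            rep = tasks.loc[tasks.index.repeat(n_r)].reset_index(drop=True)
            piece = pd.DataFrame(
                {
                    "respondent_id": np.tile(resp["respondent_id"].to_numpy(), n_t),
                    "country": np.tile(resp["country"].to_numpy(), n_t),
                    "info_type": info,
                    "block": b,
                    "task_id": rep["task_id"].to_numpy(),
                }
            )
            for a in config.attribute_names:
                piece[a] = rep[a].to_numpy()
            piece["_class"] = np.tile(resp["true_class"].to_numpy(), n_t)
            pieces.append(piece)
    long = pd.concat(pieces, ignore_index=True)
    long = long.sort_values(["respondent_id", "info_type", "task_id"]).reset_index(
        drop=True
    )
    coded = effect_code_frame(long, config)
    cls = long.pop("_class").to_numpy() - 1
    eta = model.class_asc[cls] + np.einsum("nk,nk->n", coded, model.class_betas[cls])
    long["choice"] = (rng.random(len(long)) < expit(eta)).astype(int)
    return long


def simulate_study(
    config: StudyConfig | None = None,
    model: TruePreferenceModel | None = None,
    n: int = 2000,
    seed: int = 0,
    design: Design | None = None,
    **population_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, Design]:
    """End-to-end synthetic study: population (with screening fields and
    speeders/incompletes), blocked design, and the full choice table.

    Choices are simulated for all respondents, including those the
    screening stage will later drop, mirroring a raw survey export.

    Returns ``(population, choices, design)``.
    """
    if config is None:
        config = defaults.study_config(seed)
    if model is None:
        model = defaults.four_class_model()
    if design is None:
        design = default_design(config, seed=seed)
    population = simulate_population(
        n, model=model, seed=seed, config=config, **population_kwargs
    )
    choices = simulate_choices(population, design, model, config, seed=seed + 1)
    return population, choices, design
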