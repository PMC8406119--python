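"""Post-estimation: attribute importance, scenario uptake, scale test.

Relative importance of an attribute is the spread of its level estimates
(max minus min, reference levels derived from the zero-sum constraint),
normalized by the largest spread across attributes.

Acceptance uptake of a scenario (one level per attribute) is the predicted
probability that the described data-sharing situation would be accepted:
logistic of the scenario's summed utility, with the intercept entering the
acceptance side. For a latent class model the class-adjusted uptake is the
class-probability-weighted mix of per-class uptakes.

The scale test (two-step likelihood-ratio procedure of the stated-choice
literature) asks whether two samples share preference parameters up to a
relative scale factor lambda on the second sample's utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .domain import StudyConfig, effect_code_frame, reference_level_estimate
from .latent_class import LatentClassEstimate
from .mnl import MnlEstimate, newton_logit

__all__ = [
    "relative_importance",
    "scenario_utility",
    "acceptance_uptake",
    "class_adjusted_uptake",
    "uptake_grid",
    "extreme_profiles",
    "swait_louviere_test",
    "ScaleTestResult",
]


def _level_estimates(
    source: MnlEstimate | LatentClassEstimate | dict,
    config: StudyConfig,
    cls: int | None = None,
) -> tuple[dict[str, dict[str, float]], float]:
    """Per-attribute level estimates (reference rows derived) and the asc."""
    if isinstance(source, MnlEstimate):
        get = source.coefficient
        asc = source.asc
    elif isinstance(source, LatentClassEstimate):
        c = 0 if cls is None else cls
        get = lambda a, l: source.class_coefficient(c, a, l)  # noqa: E731
        asc = float(source.class_asc[0 if cls is None else cls])
    else:  # plain {"beta": ..., "asc": ...} in canonical order
        beta = np.asarray(source["beta"], dtype=float)
        asc = float(source.get("asc", 0.0))
        cols = config.column_names()

        def get(a: str, l: str) -> float:
            attr = config.attribute(a)
            if l == attr.reference_level:
                return reference_level_estimate(
                    beta[cols.index(f"{a}[{nl}]")] for nl in attr.nonreference_levels
                )
            return float(beta[cols.index(f"{a}[{l}]")])

    table = {
        attr.name: {lvl: get(attr.name, lvl) for lvl in attr.levels}
        for attr in config.attributes
    }
    return table, asc


def relative_importance(
    source: MnlEstimate | LatentClassEstimate | dict,
    config: StudyConfig,
    cls: int | None = None,
) -> pd.DataFrame:
    """Attribute ranges (max - min level estimate) and normalized scores.

    The attribute with the largest range scores 1; all others are divided
    by that largest range.
    """
    levels, _ = _level_estimates(source, config, cls)
    rows = []
    for name, est in levels.items():
        vals = list(est.values())
        rows.append({"attribute": name, "range": max(vals) - min(vals)})
    table = pd.DataFrame(rows)
    table["importance"] = table["range"] / table["range"].max()
    return table.sort_values("importance", ascending=False).reset_index(drop=True)


def scenario_utility(
    scenario: dict[str, str],
    source: MnlEstimate | LatentClassEstimate | dict,
    config: StudyConfig,
    cls: int | None = None,
) -> float:
    """Summed utility of one scenario: intercept + per-attribute estimates."""
    levels, asc = _level_estimates(source, config, cls)
    v = asc
    for attr in config.attributes:
        if attr.name not in scenario:
            raise KeyError(f"scenario missing attribute {attr.name!r}")
        lvl = scenario[attr.name]
        if lvl not in levels[attr.name]:
            raise KeyError(f"unknown level {lvl!r} for attribute {attr.name!r}")
        v += levels[attr.name][lvl]
    return float(v)


def acceptance_uptake(v: float) -> float:
    """Predicted acceptance probability logistic(V) = 1/(1+exp(-V))."""
    return float(expit(v))


def class_adjusted_uptake(
    scenario: dict[str, str],
    lc: LatentClassEstimate,
    config: StudyConfig,
    weights: np.ndarray | None = None,
) -> float:
    """Class-probability-weighted acceptance uptake of one scenario.

    ``weights`` defaults to the model's average class probabilities.
    """
    w = lc.average_class_probability if weights is None else np.asarray(weights)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("class weights must sum to 1")
    ups = [
        acceptance_uptake(scenario_utility(scenario, lc, config, cls=c))
        for c in range(lc.n_classes)
    ]
    return float(np.dot(w, ups))


def uptake_grid(
    lc: LatentClassEstimate,
    config: StudyConfig,
    collector: str,
    new_user: str,
    weights: np.ndarray | None = None,
    as_percent: bool = True,
) -> pd.DataFrame:
    """Class-adjusted uptake for every (review, reason) x information cell
    at a fixed collector and new user — the scenario-family grid.
    """
    review = config.attribute("review").levels
    reason = config.attribute("reason").levels
    info = config.attribute("information").levels
    rows = []
    for rv in review:
        for rs in reason:
            row = {"review": rv, "reason": rs}
            for inf in info:
                scenario = {
                    "collector": collector,
                    "new_user": new_user,
                    "reason": rs,
                    "information": inf,
                    "review": rv,
                }
                u = class_adjusted_uptake(scenario, lc, config, weights)
                row[inf] = 100.0 * u if as_percent else u
            rows.append(row)
    return pd.DataFrame(rows)


def extreme_profiles(
    source: MnlEstimate | LatentClassEstimate | dict,
    config: StudyConfig,
    cls: int | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Most- and least-preferred profiles (utility is additive, so the
    per-attribute argmax/argmin levels are the global extremes)."""
    levels, _ = _level_estimates(source, config, cls)
    best = {a: max(lv, key=lv.get) for a, lv in levels.items()}
    worst = {a: min(lv, key=lv.get) for a, lv in levels.items()}
    return best, worst


# --------------------------------------------------------------------------
# Swait-Louviere scale test
# --------------------------------------------------------------------------


@dataclass
class ScaleTestResult:
    lambda_hat: float
    lr_statistic: float
    df: int
    p_value: float
    ll_a: float
    ll_b: float
    ll_pooled: float


def _fit_ll(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    theta, _, ll, _, _ = newton_logit(X, y)
    return theta, ll


def _pooled_ll_at_lambda(
    lam: float, Xa: np.ndarray, ya: np.ndarray, Xb: np.ndarray, yb: np.ndarray
) -> float:
    X = np.vstack([Xa, lam * Xb])
    y = np.concatenate([ya, yb])
    return _fit_ll(X, y)[1]


def swait_louviere_test(
    dataset_a: pd.DataFrame,
    dataset_b: pd.DataFrame,
    config: StudyConfig,
    lambda_grid: tuple[float, float] = (0.1, 5.0),
    n_grid: int = 15,
    tol: float = 1e-3,
) -> ScaleTestResult:
    """Two-step scale/preference-equality test between two samples.

    Each sample is fit separately; a pooled model constrains the
    coefficient vectors to be equal up to a scale factor lambda multiplying
    sample B's utilities. lambda is profiled over a log-spaced grid on
    ``lambda_grid`` and refined by golden-section search. The statistic
    -2 (LL_pooled(lambda_hat) - LL_a - LL_b) is referred to a chi-square
    with K+1 degrees of freedom.
    """

    def coded(ds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        X = effect_code_frame(ds, config)
        return np.column_stack([X, np.ones(len(ds))]), ds["choice"].to_numpy(float)

    Xa, ya = coded(dataset_a)
    Xb, yb = coded(dataset_b)
    # identification: both samples must vary every coded column
    for name, X in (("A", Xa), ("B", Xb)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"sample {name} does not identify all coefficients "
                "(non-overlapping or constant level usage)"
            )
    _, ll_a = _fit_ll(Xa, ya)
    _, ll_b = _fit_ll(Xb, yb)

    grid = np.geomspace(lambda_grid[0], lambda_grid[1], n_grid)
    lls = [_pooled_ll_at_lambda(l, Xa, ya, Xb, yb) for l in grid]
    j = int(np.argmax(lls))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_grid - 1)]

    # golden-section refinement on the profiled log-likelihood
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = _pooled_ll_at_lambda(c, Xa, ya, Xb, yb)
    fd = _pooled_ll_at_lambda(d, Xa, ya, Xb, yb)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _pooled_ll_at_lambda(c, Xa, ya, Xb, yb)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _pooled_ll_at_lambda(d, Xa, ya, Xb, yb)
    lam = (a + b) / 2
    ll_pooled = _pooled_ll_at_lambda(lam, Xa, ya, Xb, yb)
    lr = -2.0 * (ll_pooled - ll_a - ll_b)
    lr = max(lr, 0.0)
    df = config.k + 1
    return ScaleTestResult(
        lambda_hat=float(lam),
        lr_statistic=float(lr),
        df=df,
        p_value=float(chi2.sf(lr, df)),
        ll_a=ll_a,
        ll_b=ll_b,
        ll_pooled=ll_pooled,
    )
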