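"""Bayesian D-efficient design generation for binary accept/reject tasks.

The information matrix of the binary logit at coefficients beta is

    M(X, beta) = sum_t p_t (1 - p_t) x_t x_t'

with x_t the effect-coded task profile and p_t = logistic(asc + beta' x_t).
The D-error of a design is det(M^-1)^(1/K); the Bayesian D-error averages
it over a (quasi-random) sample from a normal prior on beta. Designs are
searched by coordinate exchange under a soft level-balance penalty and
partitioned into blocks by greedy swaps that balance level frequencies
within blocks.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import qmc, norm

from .domain import ConfigurationError, PriorSpec, StudyConfig, effect_code

__all__ = [
    "Design",
    "DesignScore",
    "IdentificationError",
    "enumerate_profiles",
    "mnl_information_matrix",
    "d_error",
    "bayesian_d_error",
    "optimize_design",
    "block_design",
    "random_design",
]

logger = logging.getLogger(__name__)


class IdentificationError(ValueError):
    """The design's information matrix is singular."""


@dataclass
class DesignScore:
    d_error: float
    bayesian_d_error: float
    level_balance_deviation: float


@dataclass
class Design:
    """A set of distinct choice tasks, optionally partitioned into blocks."""

    tasks: list[dict]
    blocks: list[list[int]] = field(default_factory=list)
    score: DesignScore | None = None

    def __post_init__(self) -> None:
        keys = [tuple(sorted(t.items())) for t in self.tasks]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("design tasks must be distinct")
        if self.blocks:
            flat = sorted(i for b in self.blocks for i in b)
            if flat != list(range(len(self.tasks))):
                raise ConfigurationError("blocks must partition the tasks exactly")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def to_frame(self, config: StudyConfig) -> pd.DataFrame:
        block_of = {}
        for b, idxs in enumerate(self.blocks):
            for i in idxs:
                block_of[i] = b + 1
        rows = []
        for i, task in enumerate(self.tasks):
            row = {"task_id": i + 1, "block": block_of.get(i, 1)}
            row.update({a: task[a] for a in config.attribute_names})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: StudyConfig) -> "Design":
        tasks = [
            {a: row[a] for a in config.attribute_names} for _, row in frame.iterrows()
        ]
        blocks: list[list[int]] = []
        if "block" in frame.columns:
            for b in sorted(frame["block"].unique()):
                blocks.append(list(np.flatnonzero((frame["block"] == b).to_numpy())))
        return cls(tasks=tasks, blocks=blocks)


def enumerate_profiles(config: StudyConfig) -> list[dict]:
    """Full factorial candidate set in lexicographic (config) order."""
    names = config.attribute_names
    level_lists = [config.attribute(n).levels for n in names]
    return [dict(zip(names, combo)) for combo in itertools.product(*level_lists)]


def _coded_matrix(design: Design, config: StudyConfig) -> np.ndarray:
    return np.array([effect_code(t, config) for t in design.tasks])


def mnl_information_matrix(
    design: Design,
    beta: np.ndarray,
    config: StudyConfig,
    asc: float = 0.0,
) -> np.ndarray:
    """Binary-logit Fisher information sum_t p(1-p) x x' over the tasks."""
    X = _coded_matrix(design, config)
    return _information_from_coded(X, np.asarray(beta, dtype=float), asc)


def _information_from_coded(X: np.ndarray, beta: np.ndarray, asc: float) -> np.ndarray:
    p = expit(asc + X @ beta)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def _d_error_from_info(M: np.ndarray, k: int) -> float:
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        raise IdentificationError(_singularity_message(M))
    return float(np.exp(-logdet / k))


def _singularity_message(M: np.ndarray) -> str:
    vals, vecs = np.linalg.eigh(M)
    null = np.flatnonzero(vals < 1e-10 * max(vals.max(), 1.0))
    cols = sorted({int(c) for j in null for c in np.flatnonzero(np.abs(vecs[:, j]) > 1e-8)})
    return f"information matrix singular; collinear/unidentified columns: {cols}"


def d_error(
    design: Design, beta: np.ndarray, config: StudyConfig, asc: float = 0.0
) -> float:
    """det(M^-1)^(1/K) at fixed coefficients; lower is more efficient."""
    M = mnl_information_matrix(design, beta, config, asc=asc)
    return _d_error_from_info(M, config.k)


def _halton_draws(priors: PriorSpec, n_draws: int, seed: int | None) -> np.ndarray:
    """Quasi-random normal draws from the prior via scrambled Halton points."""
    k = priors.k
    sampler = qmc.Halton(d=k, scramble=True, seed=seed)
    sampler.fast_forward(10)  # drop the correlated leading points
    u = sampler.random(n_draws)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    return np.asarray(priors.mean) + z * np.asarray(priors.sd)


def bayesian_d_error(
    design: Design,
    priors: PriorSpec,
    config: StudyConfig,
    n_draws: int = 500,
    seed: int | None = 0,
    asc: float = 0.0,
) -> float:
    """Mean D-error over quasi-random prior draws (Halton, inverse normal).

    Degenerate priors (all sds zero) reduce exactly to the fixed-prior
    D-error at the prior mean. A singular draw contributes +inf with a
    warning rather than aborting the average.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if priors.is_fixed:
        return d_error(design, np.asarray(priors.mean), config, asc=asc)
    X = _coded_matrix(design, config)
    draws = _halton_draws(priors, n_draws, seed)
    return _bayesian_d_error_from_coded(X, draws, config.k, asc)


def _bayesian_d_error_from_coded(
    X: np.ndarray, draws: np.ndarray, k: int, asc: float
) -> float:
    P = expit(asc + draws @ X.T)  # (R, n_tasks)
    W = P * (1.0 - P)
    M = np.einsum("rn,nk,nl->rkl", W, X, X)
    signs, logdets = np.linalg.slogdet(M)
    vals = np.where(signs > 0, np.exp(-logdets / k), np.inf)
    if np.isinf(vals).any():
        warnings.warn(
            f"{int(np.isinf(vals).sum())} singular prior draw(s) contributed +inf "
            "to the Bayesian D-error"
        )
    return float(np.mean(vals))


def level_balance_deviation(design: Design, config: StudyConfig) -> float:
    """Sum over attributes and levels of |count - n_tasks / n_levels|.

    Zero iff every level appears equally often; integer-valued whenever the
    task count is divisible by each attribute's level count.
    """
    dev = 0.0
    n = design.n_tasks
    for attr in config.attributes:
        ideal = n / attr.n_levels
        counts = {lvl: 0 for lvl in attr.levels}
        for t in design.tasks:
            counts[t[attr.name]] += 1
        dev += sum(abs(c - ideal) for c in counts.values())
    return dev


def random_design(
    config: StudyConfig, n_tasks: int, rng: np.random.Generator
) -> Design:
    """Uniformly random selection of n_tasks distinct profiles."""
    profiles = enumerate_profiles(config)
    if n_tasks > len(profiles):
        raise ConfigurationError("n_tasks exceeds the number of distinct profiles")
    idx = rng.choice(len(profiles), size=n_tasks, replace=False)
    return Design(tasks=[profiles[i] for i in idx])


def optimize_design(
    config: StudyConfig,
    priors: PriorSpec,
    n_tasks: int,
    n_iterations: int = 1000,
    seed: int = 0,
    n_draws: int = 100,
    balance_weight: float | None = None,
    asc: float = 0.0,
) -> Design:
    """Coordinate-exchange search minimizing Bayesian D-error plus a soft
    level-balance penalty.

    Parameters
    ----------
    n_iterations : int
        Budget of candidate exchanges evaluated (one evaluation = one
        single-task, single-attribute level swap).
    balance_weight : float, optional
        Penalty per unit of level-frequency deviation. Defaults to 1% of
        the initial design's Bayesian D-error, so one imbalance unit costs
        about one percent of efficiency.

    Returns the best design found, with a :class:`DesignScore` attached.
    The final penalized score never exceeds the initialization's.
    """
    rng = np.random.default_rng(seed)
    profiles = enumerate_profiles(config)
    if n_tasks > len(profiles):
        raise ConfigurationError("n_tasks exceeds the number of distinct profiles")
    draws = (
        None
        if priors.is_fixed
        else _halton_draws(priors, n_draws, int(rng.integers(2**31 - 1)))
    )
    mean_beta = np.asarray(priors.mean)

    def coded(tasks: list[dict]) -> np.ndarray:
        return np.array([effect_code(t, config) for t in tasks])

    def bd_error(tasks: list[dict]) -> float:
        X = coded(tasks)
        if draws is None:
            try:
                return _d_error_from_info(
                    _information_from_coded(X, mean_beta, asc), config.k
                )
            except IdentificationError:
                return np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _bayesian_d_error_from_coded(X, draws, config.k, asc)

    def balance(tasks: list[dict]) -> float:
        return level_balance_deviation(Design(tasks=list(tasks)), config)

    # Seeded random initialization, retried if singular.
    tasks = None
    base = np.inf
    for _ in range(20):
        cand = [profiles[i] for i in rng.choice(len(profiles), n_tasks, replace=False)]
        base = bd_error(cand)
        if np.isfinite(base):
            tasks = cand
            break
    if tasks is None:
        raise IdentificationError("could not find a nonsingular starting design")
    lam = balance_weight if balance_weight is not None else 0.01 * base
    score = base + lam * balance(tasks)
    init_score = score

    evals = 0
    improved = True
    while improved and evals < n_iterations:
        improved = False
        order = rng.permutation(n_tasks)
        for ti in order:
            for attr in config.attributes:
                current = tasks[ti][attr.name]
                for lvl in attr.levels:
                    if lvl == current or evals >= n_iterations:
                        continue
                    evals += 1
                    trial = dict(tasks[ti])
                    trial[attr.name] = lvl
                    key = tuple(sorted(trial.items()))
                    if any(
                        tuple(sorted(t.items())) == key
                        for j, t in enumerate(tasks)
                        if j != ti
                    ):
                        continue  # keep tasks distinct
                    new_tasks = tasks[: ti] + [trial] + tasks[ti + 1 :]
                    new_score = bd_error(new_tasks) + lam * balance(new_tasks)
                    if new_score < score - 1e-12:
                        tasks, score = new_tasks, new_score
                        improved = True
            if evals >= n_iterations:
                break
    assert score <= init_score + 1e-9

    design = Design(tasks=tasks)
    bde = bd_error(tasks)
    try:
        fixed = d_error(design, mean_beta, config, asc=asc)
    except IdentificationError:
        fixed = float("inf")
    design.score = DesignScore(
        d_error=fixed,
        bayesian_d_error=bde,
        level_balance_deviation=balance(tasks),
    )
    logger.info(
        "optimized %d-task design: D-error %.4f, Bayesian %.4f, imbalance %.1f "
        "(%d exchanges evaluated)",
        n_tasks, fixed, bde, design.score.level_balance_deviation, evals,
    )
    return design


def block_design(design: Design, n_blocks: int, config: StudyConfig, seed: int = 0) -> Design:
    """Partition tasks into equal blocks by greedy swaps balancing per-block
    level frequencies."""
    n = design.n_tasks
    if n % n_blocks != 0:
        raise ConfigurationError(
            f"{n} tasks cannot be split evenly into {n_blocks} blocks"
        )
    per = n // n_blocks
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for b in range(n_blocks):
        assign[order[b * per : (b + 1) * per]] = b

    X = np.array(
        [
            [
                1.0 if t[a.name] == lvl else 0.0
                for a in config.attributes
                for lvl in a.levels
            ]
            for t in design.tasks
        ]
    )
    n_levels = np.array([a.n_levels for a in config.attributes for _ in a.levels])
    ideal = per / n_levels  # per block, per level column

    def cost(a: np.ndarray) -> float:
        tot = 0.0
        for b in range(n_blocks):
            counts = X[a == b].sum(axis=0)
            tot += np.abs(counts - ideal).sum()
        return tot

    current = cost(assign)
    improved = True
    sweeps = 0
    while improved and sweeps < 50:
        improved = False
        sweeps += 1
        for i in range(n):
            for j in range(i + 1, n):
                if assign[i] == assign[j]:
                    continue
                assign[i], assign[j] = assign[j], assign[i]
                c = cost(assign)
                if c < current - 1e-12:
                    current = c
                    improved = True
                else:
                    assign[i], assign[j] = assign[j], assign[i]
    blocks = [list(np.flatnonzero(assign == b)) for b in range(n_blocks)]
    return Design(tasks=list(design.tasks), blocks=blocks, score=design.score)
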