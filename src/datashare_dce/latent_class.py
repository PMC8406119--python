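"""Latent class binary logit with a country-driven class-membership model.

Respondents belong to one of C latent preference classes. Given class c, a
respondent's 16 accept/reject answers are independent Bernoulli draws with
P(accept) = logistic(asc_c + beta_c' x). Class membership follows a
multinomial logit on respondent covariates (here: country, with the last
class as reference and the United Kingdom as reference country):

    pi_rc = softmax_c( alpha_c + gamma_c' country_r ),  alpha_C = gamma_C = 0.

Estimation is EM with seeded random multistarts, followed by a quasi-Newton
polish of the observed-data log-likelihood. Because country is the only
membership covariate, the membership M-step is a saturated multinomial fit
with a closed form (per-country log-odds of mean posteriors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .domain import StudyConfig, effect_code_frame, reference_level_estimate
from .mnl import MnlEstimate, SeparationError, fit_binary_logit, newton_logit

__all__ = [
    "LCData",
    "LCParams",
    "LatentClassEstimate",
    "prepare",
    "e_step",
    "m_step",
    "observed_loglik",
    "fit_latent_class",
    "select_n_classes",
]

logger = logging.getLogger(__name__)

_POST_FLOOR = 1e-8


@dataclass
class LCData:
    """Choice data regrouped by respondent for mixture estimation."""

    X: np.ndarray            # (n_obs, K) effect-coded profiles
    y: np.ndarray            # (n_obs,)
    starts: np.ndarray       # (n_resp + 1,) obs slice boundaries per respondent
    Z: np.ndarray            # (n_resp, 1 + n_countries - 1) membership covariates
    respondent_ids: np.ndarray
    countries: tuple[str, ...]          # membership column countries (non-ref)
    reference_country: str
    country_of: np.ndarray   # (n_resp,) country label per respondent

    @property
    def n_resp(self) -> int:
        return len(self.starts) - 1

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class LCParams:
    class_betas: np.ndarray   # (C, K)
    class_asc: np.ndarray     # (C,)
    membership: np.ndarray    # (C-1, Z columns); empty for C=1

    @property
    def n_classes(self) -> int:
        return self.class_betas.shape[0]

    def copy(self) -> "LCParams":
        return LCParams(
            self.class_betas.copy(), self.class_asc.copy(), self.membership.copy()
        )


def prepare(
    dataset: pd.DataFrame,
    config: StudyConfig,
    reference_country: str = "uk",
) -> LCData:
    """Sort by respondent and precompute coded matrices and covariates."""
    df = dataset.sort_values("respondent_id", kind="stable").reset_index(drop=True)
    X = effect_code_frame(df, config)
    y = df["choice"].to_numpy(dtype=float)
    rid = df["respondent_id"].to_numpy()
    change = np.flatnonzero(np.diff(rid) != 0) + 1
    starts = np.concatenate([[0], change, [len(df)]])
    first = starts[:-1]
    resp_ids = rid[first]
    country_of = df["country"].to_numpy()[first]
    preferred = ("sweden", "norway", "iceland")
    seen = {c for c in pd.unique(country_of) if c != reference_country}
    present = [c for c in preferred if c in seen]
    present += sorted(seen - set(present))
    Z = np.ones((len(first), 1 + len(present)))
    for j, c in enumerate(present):
        Z[:, 1 + j] = (country_of == c).astype(float)
    return LCData(
        X=X,
        y=y,
        starts=starts,
        Z=Z,
        respondent_ids=resp_ids,
        countries=tuple(present),
        reference_country=reference_country,
        country_of=country_of,
    )


def _log_prior(params: LCParams, data: LCData) -> np.ndarray:
    """(n_resp, C) log class-membership probabilities."""
    C = params.n_classes
    if C == 1:
        return np.zeros((data.n_resp, 1))
    logits = np.column_stack(
        [data.Z @ params.membership.T, np.zeros(data.n_resp)]
    )
    return logits - logsumexp(logits, axis=1, keepdims=True)


def _resp_class_loglik(params: LCParams, data: LCData) -> np.ndarray:
    """(n_resp, C) log P(respondent's choices | class)."""
    eta = data.class_eta(params) if hasattr(data, "class_eta") else (
        params.class_asc[None, :] + data.X @ params.class_betas.T
    )
    ll_obs = np.where(
        data.y[:, None] == 1.0,
        -np.logaddexp(0.0, -eta),
        -np.logaddexp(0.0, eta),
    )
    return np.add.reduceat(ll_obs, data.starts[:-1], axis=0)


def e_step(params: LCParams, data: LCData) -> tuple[np.ndarray, float]:
    """Posterior class probabilities and the observed-data log-likelihood.

    posterior_rc is proportional to pi_c(covariates_r) times the product of
    the respondent's class-conditional choice probabilities; rows are
    normalized in log space (log-sum-exp).
    """
    log_joint = _log_prior(params, data) + _resp_class_loglik(params, data)
    norm = logsumexp(log_joint, axis=1, keepdims=True)
    posterior = np.exp(log_joint - norm)
    return posterior, float(norm.sum())


def observed_loglik(params: LCParams, data: LCData) -> float:
    return e_step(params, data)[1]


def _membership_closed_form(posterior: np.ndarray, data: LCData) -> np.ndarray:
    """Weighted multinomial-logit MLE of class membership on country.

    With a constant plus one dummy per non-reference country the model is
    saturated over the observed country patterns, so the MLE is the
    per-country log-odds of the mean posterior against the last class.
    """
    C = posterior.shape[1]
    if C == 1:
        return np.zeros((0, data.Z.shape[1]))
    logits_by_pattern = {}
    for country in (data.reference_country, *data.countries):
        mask = data.country_of == country
        if not mask.any():
            logits_by_pattern[country] = np.zeros(C - 1)
            continue
        shares = posterior[mask].mean(axis=0)
        shares = np.clip(shares, _POST_FLOOR, None)
        logits_by_pattern[country] = np.log(shares[:-1] / shares[-1])
    ref = logits_by_pattern[data.reference_country]
    coefs = np.zeros((C - 1, data.Z.shape[1]))
    coefs[:, 0] = ref
    for j, country in enumerate(data.countries):
        coefs[:, 1 + j] = logits_by_pattern[country] - ref
    return coefs


def m_step(
    posterior: np.ndarray,
    data: LCData,
    prev: LCParams,
    degenerate_floor: float = 1e-3,
) -> LCParams:
    """Posterior-weighted logit update per class + membership update.

    Each class update maximizes the expected complete-data log-likelihood
    (weighted Newton, warm-started at the previous parameters). A class
    whose posterior mass falls below ``degenerate_floor`` of respondents is
    kept but refit with a ridge-stabilized update.
    """
    C = posterior.shape[1]
    Xa = np.column_stack([data.X, np.ones(len(data.y))])
    betas = prev.class_betas.copy()
    ascs = prev.class_asc.copy()
    counts = np.diff(data.starts)
    for c in range(C):
        w = np.repeat(posterior[:, c], counts)
        mass = posterior[:, c].sum()
        ridge = 0.0
        if mass < degenerate_floor * data.n_resp:
            logger.warning(
                "class %d nearly empty (mass %.3g); ridge-stabilized update", c + 1, mass
            )
            ridge = 1e-3
        start = np.append(betas[c], ascs[c])
        try:
            theta, *_ = newton_logit(Xa, data.y, weights=w, start=start,
                                     tol=1e-8, max_iter=50, ridge=ridge)
        except SeparationError:
            logger.warning("class %d update separated; retrying with ridge", c + 1)
            theta, *_ = newton_logit(Xa, data.y, weights=w, start=start,
                                     tol=1e-8, max_iter=50, ridge=1e-3)
        betas[c] = theta[:-1]
        ascs[c] = theta[-1]
    membership = _membership_closed_form(posterior, data)
    return LCParams(betas, ascs, membership)


# --------------------------------------------------------------------------
# Observed-likelihood objective for the quasi-Newton polish
# --------------------------------------------------------------------------


def _pack(params: LCParams) -> np.ndarray:
    return np.concatenate(
        [params.class_betas.ravel(), params.class_asc, params.membership.ravel()]
    )


def _unpack(theta: np.ndarray, C: int, K: int, zcols: int) -> LCParams:
    nb = C * K
    betas = theta[:nb].reshape(C, K)
    ascs = theta[nb : nb + C]
    memb = theta[nb + C :].reshape(max(C - 1, 0), zcols)
    return LCParams(betas, ascs, memb)


def _neg_loglik_and_grad(theta: np.ndarray, data: LCData, C: int):
    params = _unpack(theta, C, data.k, data.Z.shape[1])
    posterior, ll = e_step(params, data)
    counts = np.diff(data.starts)
    eta = params.class_asc[None, :] + data.X @ params.class_betas.T
    resid = data.y[:, None] - expit(eta)          # (n_obs, C)
    w = np.repeat(posterior, counts, axis=0)      # (n_obs, C)
    wr = w * resid
    g_beta = wr.T @ data.X                        # (C, K)
    g_asc = wr.sum(axis=0)                        # (C,)
    if C > 1:
        prior = np.exp(_log_prior(params, data))
        g_memb = (posterior - prior)[:, :-1].T @ data.Z
    else:
        g_memb = np.zeros((0, data.Z.shape[1]))
    grad = np.concatenate([g_beta.ravel(), g_asc, g_memb.ravel()])
    return -ll, -grad


def _polish(params: LCParams, data: LCData, maxiter: int = 200) -> tuple[LCParams, float]:
    C = params.n_classes
    res = minimize(
        _neg_loglik_and_grad,
        _pack(params),
        args=(data, C),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    polished = _unpack(res.x, C, data.k, data.Z.shape[1])
    ll = -res.fun
    base = observed_loglik(params, data)
    if ll < base:  # never accept a worse point than EM's
        return params, base
    return polished, float(ll)


# --------------------------------------------------------------------------
# Results container
# --------------------------------------------------------------------------


@dataclass
class LatentClassEstimate:
    n_classes: int
    class_betas: np.ndarray             # (C, K), classes in canonical order
    class_asc: np.ndarray               # (C,)
    membership_coefs: np.ndarray        # (C-1, 1 + n_countries - 1)
    membership_countries: tuple[str, ...]
    average_class_probability: np.ndarray
    posterior: np.ndarray               # (n_resp, C)
    respondent_ids: np.ndarray
    log_likelihood: float
    aic: float
    bic: float
    n_parameters: int
    n_obs: int
    converged: bool
    config: StudyConfig = field(repr=False)
    class_se: np.ndarray | None = None  # (C, K+1), asc last
    membership_se: np.ndarray | None = None

    def class_coefficient(self, cls: int, attribute: str, level: str) -> float:
        attr = self.config.attribute(attribute)
        cols = self.config.column_names()
        if level == attr.reference_level:
            return reference_level_estimate(
                self.class_betas[cls, cols.index(f"{attribute}[{l}]")]
                for l in attr.nonreference_levels
            )
        return float(self.class_betas[cls, cols.index(f"{attribute}[{level}]")])

    def prior_shares(self, country: str) -> np.ndarray:
        """Membership-model class shares for one country (alternative to the
        mean-posterior average class probability)."""
        if self.n_classes == 1:
            return np.array([1.0])
        x = np.zeros(self.membership_coefs.shape[1])
        x[0] = 1.0
        if country in self.membership_countries:
            x[1 + self.membership_countries.index(country)] = 1.0
        logits = np.append(self.membership_coefs @ x, 0.0)
        e = np.exp(logits - logits.max())
        return e / e.sum()

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "class_betas": self.class_betas.tolist(),
            "class_asc": self.class_asc.tolist(),
            "membership_coefs": self.membership_coefs.tolist(),
            "membership_countries": list(self.membership_countries),
            "average_class_probability": self.average_class_probability.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "n_parameters": self.n_parameters,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "column_names": self.config.column_names(),
        }


def n_parameters(C: int, K: int, n_countries: int) -> int:
    """C (K+1) choice parameters plus (C-1)(1 + n_countries - 1) membership."""
    memb = (C - 1) * (1 + n_countries - 1) if C > 1 else 0
    return C * (K + 1) + memb


def _canonical_order(params: LCParams, posterior: np.ndarray, data: LCData):
    """Reorder classes by descending average posterior probability.

    The membership block is re-expressed against the new last class; this
    is exact because the model is saturated in the country patterns.
    """
    C = params.n_classes
    avg = posterior.mean(axis=0)
    order = np.argsort(-avg, kind="stable")
    betas = params.class_betas[order]
    ascs = params.class_asc[order]
    post = posterior[:, order]
    if C == 1:
        return LCParams(betas, ascs, params.membership), post
    # per-pattern prior logits (reference class appended as 0), permuted
    zcols = params.membership.shape[1]
    patterns = [("__ref__", np.eye(zcols)[0])] + [
        ("c_" + c, np.eye(zcols)[0] + np.eye(zcols)[1 + j])
        for j, c in enumerate(data.countries)
    ]
    new_memb = np.zeros((C - 1, zcols))
    logits_new = {}
    for name, z in patterns:
        logits = np.append(params.membership @ z, 0.0)[order]
        logits_new[name] = logits[:-1] - logits[-1]
    new_memb[:, 0] = logits_new["__ref__"]
    for j, c in enumerate(data.countries):
        new_memb[:, 1 + j] = logits_new["c_" + c] - logits_new["__ref__"]
    return LCParams(betas, ascs, new_memb), post


def _random_init(data: LCData, C: int, rng: np.random.Generator) -> np.ndarray:
    """Random Dirichlet responsibilities to seed a first M-step."""
    return rng.dirichlet(np.ones(C), size=data.n_resp)


def _run_em(
    data: LCData,
    C: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[LCParams, float, bool]:
    posterior = _random_init(data, C, rng)
    params = LCParams(
        class_betas=np.zeros((C, data.k)),
        class_asc=np.zeros(C),
        membership=np.zeros((max(C - 1, 0), data.Z.shape[1])),
    )
    params = m_step(posterior, data, params)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        posterior, ll = e_step(params, data)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
        params = m_step(posterior, data, params)
    else:
        posterior, ll = e_step(params, data)
    return params, ll, converged


def _standard_errors(params: LCParams, data: LCData):
    """Wald SEs from a numerical Hessian of the observed log-likelihood.

    Central differences on the analytic gradient; adequate for reporting,
    and skipped silently if the Hessian is not invertible.
    """
    theta0 = _pack(params)
    C = params.n_classes
    p = len(theta0)
    H = np.zeros((p, p))
    h = 1e-5
    for j in range(p):
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _neg_loglik_and_grad(tp, data, C)
        _, gm = _neg_loglik_and_grad(tm, data, C)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return None, None
    nb = C * data.k
    class_se = np.column_stack(
        [se[:nb].reshape(C, data.k), se[nb : nb + C]]
    )
    memb_se = se[nb + C :].reshape(max(C - 1, 0), data.Z.shape[1])
    return class_se, memb_se


def fit_latent_class(
    dataset: pd.DataFrame,
    config: StudyConfig,
    n_classes: int,
    n_starts: int = 100,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    polish: bool = True,
    compute_se: bool = False,
    reference_country: str = "uk",
) -> LatentClassEstimate:
    """Fit the C-class mixture by multistart EM + quasi-Newton polish.

    The best of ``n_starts`` seeded random initializations is kept; classes
    are reported in descending average-posterior order. Deterministic given
    ``seed``. ``n_classes=1`` coincides with the pooled binary logit.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    data = prepare(dataset, config, reference_country=reference_country)
    if n_classes > 1 and data.n_resp < n_classes:
        raise ValueError(
            f"{data.n_resp} respondent(s) cannot identify {n_classes} classes"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, LCParams] | None = None
    failures = []
    n_runs = 1 if n_classes == 1 else n_starts
    any_converged = False
    for s in range(n_runs):
        try:
            params, ll, conv = _run_em(data, n_classes, rng, tol, max_iter)
            any_converged = any_converged or conv
            if best is None or ll > best[0]:
                best = (ll, params)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(f"start {s}: {exc}")
    if best is None:
        raise RuntimeError(
            "all EM starts failed:\n" + "\n".join(failures[:10])
        )
    ll, params = best
    if polish:
        params, ll = _polish(params, data)
    posterior, ll = e_step(params, data)
    params, posterior = _canonical_order(params, posterior, data)

    n_countries = 1 + len(data.countries)
    npar = n_parameters(n_classes, data.k, n_countries)
    class_se = memb_se = None
    if compute_se:
        class_se, memb_se = _standard_errors(params, data)
    return LatentClassEstimate(
        n_classes=n_classes,
        class_betas=params.class_betas,
        class_asc=params.class_asc,
        membership_coefs=params.membership,
        membership_countries=data.countries,
        average_class_probability=posterior.mean(axis=0),
        posterior=posterior,
        respondent_ids=data.respondent_ids,
        log_likelihood=ll,
        aic=2 * npar - 2 * ll,
        bic=npar * np.log(len(data.y)) - 2 * ll,
        n_parameters=npar,
        n_obs=len(data.y),
        converged=any_converged,
        config=config,
        class_se=class_se,
        membership_se=memb_se,
    )


def lc_from_mnl(est: MnlEstimate, dataset: pd.DataFrame, config: StudyConfig):
    """View a pooled fit as a single-class estimate (C=1 identity)."""
    data = prepare(dataset, config)
    return LatentClassEstimate(
        n_classes=1,
        class_betas=est.beta[None, :],
        class_asc=np.array([est.asc]),
        membership_coefs=np.zeros((0, data.Z.shape[1])),
        membership_countries=data.countries,
        average_class_probability=np.array([1.0]),
        posterior=np.ones((data.n_resp, 1)),
        respondent_ids=data.respondent_ids,
        log_likelihood=est.log_likelihood,
        aic=est.aic,
        bic=(est.k + 1) * np.log(est.n_obs) - 2 * est.log_likelihood,
        n_parameters=est.k + 1,
        n_obs=est.n_obs,
        converged=est.converged,
        config=config,
    )


def select_n_classes(
    dataset: pd.DataFrame,
    config: StudyConfig,
    c_range,
    n_starts: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Model-comparison table over class counts: LL, AIC, BIC, parameters.

    Per-C fit errors are recorded in the table instead of aborting it; the
    AIC-minimizing row is flagged ``best``.
    """
    rows = []
    for C in c_range:
        row: dict = {"n_classes": C}
        try:
            fit = fit_latent_class(
                dataset, config, C, n_starts=n_starts, seed=seed, **fit_kwargs
            )
            row.update(
                log_likelihood=fit.log_likelihood,
                aic=fit.aic,
                bic=fit.bic,
                n_parameters=fit.n_parameters,
                error=None,
            )
        except Exception as exc:  # noqa: BLE001 - reported per row
            row.update(
                log_likelihood=np.nan, aic=np.nan, bic=np.nan,
                n_parameters=np.nan, error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["aic"].notna().any():
        table["best"] = table["aic"] == table["aic"].min()
    else:
        table["best"] = False
    return table
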