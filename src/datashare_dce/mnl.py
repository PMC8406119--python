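"""Maximum-likelihood binary (accept/reject) logit with effect coding.

The model: P(accept) = logistic(asc + beta' x), with x the effect-coded
task profile. The intercept `asc` is reported alongside the K level
estimates; reference-level rows of the report are derived from the
zero-sum constraint, never estimated.

Estimation is Newton-Raphson on the (globally concave) log-likelihood with
step-halving, Wald standard errors from the inverse observed Hessian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .domain import StudyConfig, effect_code_frame, reference_level_estimate

__all__ = [
    "MnlEstimate",
    "SeparationError",
    "log_likelihood",
    "fit_binary_logit",
    "country_stratified_fits",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a column perfectly separates choices."""


@dataclass
class MnlEstimate:
    """Fitted pooled logit in the shape of the published estimates table.

    ``beta``/``se``/``ci95``/``p_values`` are ordered with the intercept
    *last* (index K), matching ``config.column_names() + ["intercept"]``.
    """

    beta: np.ndarray          # K level estimates
    asc: float                # intercept (acceptance constant)
    se: np.ndarray            # K+1, intercept last
    ci95: np.ndarray          # (K+1, 2)
    p_values: np.ndarray      # K+1
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    config: StudyConfig = field(repr=False)
    n_iter: int = 0

    @property
    def k(self) -> int:
        return len(self.beta)

    def coefficient(self, attribute: str, level: str) -> float:
        """Level estimate; reference levels via the zero-sum derivation."""
        attr = self.config.attribute(attribute)
        cols = self.config.column_names()
        if level == attr.reference_level:
            return reference_level_estimate(
                self.beta[cols.index(f"{attribute}[{l}]")]
                for l in attr.nonreference_levels
            )
        return float(self.beta[cols.index(f"{attribute}[{level}]")])

    def level_table(self) -> pd.DataFrame:
        """Per-level rows incl. derived reference rows (SE/CI/p not applicable)."""
        rows = []
        cols = self.config.column_names()
        for attr in self.config.attributes:
            for lvl in attr.levels:
                is_ref = lvl == attr.reference_level
                if is_ref:
                    rows.append(
                        {
                            "attribute": attr.name,
                            "level": lvl,
                            "estimate": self.coefficient(attr.name, lvl),
                            "se": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p_value": np.nan,
                            "reference": True,
                        }
                    )
                else:
                    j = cols.index(f"{attr.name}[{lvl}]")
                    rows.append(
                        {
                            "attribute": attr.name,
                            "level": lvl,
                            "estimate": float(self.beta[j]),
                            "se": float(self.se[j]),
                            "ci_low": float(self.ci95[j, 0]),
                            "ci_high": float(self.ci95[j, 1]),
                            "p_value": float(self.p_values[j]),
                            "reference": False,
                        }
                    )
        rows.append(
            {
                "attribute": "intercept",
                "level": "",
                "estimate": self.asc,
                "se": float(self.se[-1]),
                "ci_low": float(self.ci95[-1, 0]),
                "ci_high": float(self.ci95[-1, 1]),
                "p_value": float(self.p_values[-1]),
                "reference": False,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "levels": self.level_table().to_dict(orient="records"),
            "beta": self.beta.tolist(),
            "asc": self.asc,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "column_names": self.config.column_names(),
        }


def _design_matrix(dataset: pd.DataFrame, config: StudyConfig):
    X = effect_code_frame(dataset, config)
    y = dataset["choice"].to_numpy(dtype=float)
    return X, y


def log_likelihood(
    beta: np.ndarray, asc: float, dataset: pd.DataFrame, config: StudyConfig
) -> float:
    """Bernoulli log-likelihood of the accept/reject data at (beta, asc)."""
    X, y = _design_matrix(dataset, config)
    return _loglik(np.asarray(beta, dtype=float), asc, X, y)


def _loglik(beta: np.ndarray, asc: float, X: np.ndarray, y: np.ndarray) -> float:
    eta = asc + X @ beta
    # log(p) and log(1-p) via the numerically stable log-logistic forms
    return float(np.sum(y * -np.logaddexp(0.0, -eta) + (1 - y) * -np.logaddexp(0.0, eta)))


def newton_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    ridge: float = 0.0,
):
    """Weighted Newton-Raphson logistic regression on a design matrix that
    already includes any intercept column.

    Returns ``(theta, hessian, loglik, converged, n_iter)``. ``ridge`` adds
    a small quadratic penalty for degenerate (near-empty) weighted fits.
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    theta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()

    def f(t):
        eta = X @ t
        ll = np.sum(w * (y * -np.logaddexp(0.0, -eta) + (1 - y) * -np.logaddexp(0.0, eta)))
        return ll - 0.5 * ridge * t @ t

    ll = f(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_hat = expit(X @ theta)
        grad = X.T @ (w * (y - p_hat)) - ridge * theta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        wdiag = w * p_hat * (1 - p_hat) + 1e-12
        H = (X * wdiag[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        if np.max(np.abs(step)) < 1e-10:
            # gradient is at the floating-point noise floor for this n
            converged = True
            break
        # step-halving keeps the log-likelihood strictly non-decreasing
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            ll_new = f(cand)
            if ll_new >= ll - 1e-12:
                theta, ll = cand, ll_new
                break
            alpha *= 0.5
        else:  # pragma: no cover - pathological
            break
        if np.max(np.abs(theta)) > 30:
            j = int(np.argmax(np.abs(theta)))
            raise SeparationError(
                f"coefficient {j} diverging (|theta|>30): data are (quasi-)separated"
            )
    p_hat = expit(X @ theta)
    wdiag = w * p_hat * (1 - p_hat) + 1e-12
    H = (X * wdiag[:, None]).T @ X + ridge * np.eye(p)
    return theta, H, ll, converged, it


def fit_binary_logit(
    dataset: pd.DataFrame,
    config: StudyConfig,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MnlEstimate:
    """Fit the pooled accept/reject logit and return the estimates table.

    Raises :class:`SeparationError` when all choices are identical or a
    coefficient diverges (complete separation); flags (rather than hides)
    non-convergence.
    """
    X, y = _design_matrix(dataset, config)
    if y.min() == y.max():
        raise SeparationError(
            "dataset contains only "
            + ("accepts" if y[0] == 1 else "rejects")
            + "; the intercept is unbounded"
        )
    Xa = np.column_stack([X, np.ones(len(y))])  # intercept last
    theta, H, ll, converged, it = newton_logit(Xa, y, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(f"binary logit did not converge in {max_iter} iterations")
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = theta / se
    p = 2 * norm.sf(np.abs(z))
    ci = np.column_stack([theta - 1.96 * se, theta + 1.96 * se])
    k1 = Xa.shape[1]
    return MnlEstimate(
        beta=theta[:-1],
        asc=float(theta[-1]),
        se=se,
        ci95=ci,
        p_values=p,
        log_likelihood=ll,
        aic=2 * k1 - 2 * ll,
        n_obs=len(y),
        converged=converged,
        config=config,
        n_iter=it,
    )


def country_stratified_fits(
    dataset: pd.DataFrame,
    config: StudyConfig,
    min_obs: int = 50,
) -> dict[str, MnlEstimate]:
    """Fit the binary logit separately per country.

    Strata with fewer than ``min_obs`` rows (or with degenerate choices)
    are skipped with a logged warning rather than failing the whole run.
    """
    fits: dict[str, MnlEstimate] = {}
    for country, sub in dataset.groupby("country"):
        if len(sub) < min_obs:
            logger.warning(
                "skipping stratum %r: only %d observations (< %d)",
                country, len(sub), min_obs,
            )
            continue
        try:
            fits[country] = fit_binary_logit(sub, config)
        except SeparationError as exc:
            logger.warning("skipping stratum %r: %s", country, exc)
    return fits
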