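"""Survey-weighted logistic regression by Newton-Raphson.

Point estimates solve the probability-weighted score equations

    sum_i w_i (y_i - p_i) x_i = 0,    p_i = logistic(x_i' beta),

so weights enter as sampling (probability) weights.  The default
covariance is the sandwich estimator H^-1 (sum_i w_i^2 s_i s_i') H^-1
with H the weighted observed information; a model-based H^-1 and an
optional cluster-robust sandwich are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core_data import ContractError, DesignMatrix, InvalidInputError, NutridecompError

__all__ = [
    "LogitFit",
    "ConvergenceError",
    "SeparationError",
    "CollinearityError",
    "fit",
    "predict_mean",
]

MAX_ITER = 100
SCORE_TOL = 1e-8
MAX_HALVINGS = 10
SEPARATION_BOUND = 30.0


class ConvergenceError(NutridecompError):
    """Newton-Raphson failed to converge; carries the last iterate."""

    def __init__(self, msg, beta=None):
        super().__init__(msg)
        self.beta = beta


class SeparationError(NutridecompError):
    """Quasi-complete separation detected (a coefficient is diverging)."""


class CollinearityError(NutridecompError):
    """The weighted information matrix is numerically singular."""


@dataclass
class LogitFit:
    """A fitted weighted logistic regression.

    ``beta`` is ordered as the design columns (intercept first); ``cov``
    is the requested covariance matrix; ``columns``/``groups`` are carried
    over from the design so downstream stages can map coefficients back to
    categorical variables.
    """

    beta: np.ndarray
    cov: np.ndarray
    n_obs: int
    converged: bool
    iterations: int
    loglik: float
    columns: list[str]
    groups: dict[str, list[int]]

    @property
    def n_params(self) -> int:
        return len(self.beta)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _loglik(beta, X, y, w):
    eta = X @ beta
    # numerically stable weighted Bernoulli log-likelihood
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit(design: DesignMatrix, covariance: str = "sandwich",
        cluster: np.ndarray | None = None) -> LogitFit:
    """Maximize the weighted Bernoulli log-likelihood.

    Parameters
    ----------
    design
        Dummy-coded design with outcome and weights.
    covariance
        ``"sandwich"`` (default), ``"model"`` (inverse information), or
        ``"cluster"`` (requires ``cluster`` labels, one per row).
    cluster
        Cluster labels for the cluster-robust sandwich.

    Raises
    ------
    ConvergenceError, SeparationError, CollinearityError
    """
    X = design.values
    y = design.outcome
    w = design.weights
    if not np.isin(y, [0.0, 1.0]).all():
        raise InvalidInputError("outcome must be binary 0/1")
    if w.sum() <= 0:
        raise InvalidInputError("weights must have positive sum")
    if covariance not in ("sandwich", "model", "cluster"):
        raise InvalidInputError(f"unknown covariance {covariance!r}")
    if covariance == "cluster" and cluster is None:
        raise ContractError("cluster covariance requested without cluster labels")

    n, k = X.shape
    pbar = float((w * y).sum() / w.sum())
    pbar = min(max(pbar, 1e-10), 1 - 1e-10)
    beta = np.zeros(k)
    beta[0] = np.log(pbar / (1 - pbar))

    ll = _loglik(beta, X, y, w)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        score = X.T @ (w * (y - p))
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        info = X.T @ (X * (w * p * (1 - p))[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("singular weighted information matrix") from exc
        # step-halving keeps the likelihood non-decreasing, up to the
        # rounding noise of a large weighted sum
        ll_slack = 1e-9 * (1.0 + abs(ll))
        new_ll = None
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + step
            cand_ll = _loglik(cand, X, y, w)
            if cand_ll >= ll - ll_slack:
                beta, ll, new_ll = cand, cand_ll, cand_ll
                break
            step = step / 2.0
        if new_ll is None:
            raise ConvergenceError("step-halving failed to improve likelihood",
                                   beta=beta)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficient exceeded %.0f; data are (quasi-)separated"
                % SEPARATION_BOUND
            )
    if not converged:
        p = expit(X @ beta)
        score = X.T @ (w * (y - p))
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
        else:
            raise ConvergenceError(
                f"no convergence in {MAX_ITER} iterations "
                f"(max |score| = {np.max(np.abs(score)):.3g})", beta=beta)

    p = expit(X @ beta)
    info = X.T @ (X * (w * p * (1 - p))[:, None])
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("singular information at the optimum") from exc

    if covariance == "model":
        cov = bread
    else:
        resid = (w * (y - p))[:, None] * X  # rows are w_i * s_i
        if covariance == "cluster":
            cluster = np.asarray(cluster)
            if cluster.shape[0] != n:
                raise ContractError("cluster labels length mismatch")
            _, inv = np.unique(cluster, return_inverse=True)
            g = np.zeros((inv.max() + 1, k))
            np.add.at(g, inv, resid)
            meat = g.T @ g
        else:
            meat = resid.T @ resid
        cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2.0

    return LogitFit(
        beta=beta,
        cov=cov,
        n_obs=n,
        converged=converged,
        iterations=it,
        loglik=ll,
        columns=list(design.columns),
        groups={kk: list(v) for kk, v in design.groups.items()},
    )


def predict_mean(fit_: LogitFit, design: DesignMatrix) -> float:
    """Weighted mean predicted probability sum w*logistic(x'beta) / sum w."""
    if design.n_cols != fit_.n_params:
        raise ContractError(
            f"design has {design.n_cols} columns, fit expects {fit_.n_params}"
        )
    w = design.weights
    return float((w * expit(design.values @ fit_.beta)).sum() / w.sum())
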