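"""l1+l2-regularized least-squares classifier (elastic-net type).

The model is a linear score f(x) = beta . x whose sign assigns a sample to
one of two classes. The weight vector minimizes

    (1/n) ||Y - X beta||^2  +  tau ||beta||_1  +  lambda ||beta||^2

where the l1 weight tau induces exact zeros (variable selection) and the
l2 weight lambda stabilizes the solution and lets correlated variables
enter together. Optimization is damped iterative soft-thresholding:

    beta_{k+1} = S_{tau/(2 sigma)}( [beta_k (sigma - lambda)
                                     + (1/n) X^T (Y - X beta_k)] / sigma )

with step constant sigma >= lambda + ||X^T X||_2 / n, which guarantees a
monotonically non-increasing objective, and S the component-wise
soft-threshold. No intercept is fit: columns are expected standardized and
labels are +-1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetModel",
    "fit_l1l2",
    "refit_on_support",
    "predict",
    "tau_max",
    "make_tau_grid",
    "gram_spectral_norm",
    "kkt_residual",
    "objective",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000


@dataclass
class ElasticNetModel:
    beta: np.ndarray
    tau: float
    lambda_: float
    n_iter: int
    converged: bool
    objective: float
    objective_history: np.ndarray = field(repr=False, default=None)
    gene_ids: list[str] | None = None
    fallback_label: int | None = None  # set when fitted on an empty support

    @property
    def support(self) -> np.ndarray:
        """Indices of non-zero weights."""
        return np.flatnonzero(self.beta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "tau": self.tau,
                "lambda": self.lambda_,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "objective": self.objective,
                "gene_ids": self.gene_ids,
                "fallback_label": self.fallback_label,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ElasticNetModel":
        d = json.loads(text)
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            tau=d["tau"],
            lambda_=d["lambda"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            objective=d["objective"],
            gene_ids=d.get("gene_ids"),
            fallback_label=d.get("fallback_label"),
        )


def objective(X: np.ndarray, Y: np.ndarray, beta: np.ndarray, tau: float, lambda_: float) -> float:
    n = X.shape[0]
    r = Y - X @ beta
    return float(
        r @ r / n + tau * np.abs(beta).sum() + lambda_ * beta @ beta
    )


def gram_spectral_norm(X: np.ndarray) -> float:
    """||X^T X||_2 = (largest singular value of X)^2."""
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[0] ** 2) if s.size else 0.0


def tau_max(X: np.ndarray, Y: np.ndarray) -> float:
    """Smallest tau for which beta = 0 solves the problem: 2 ||X^T Y||_inf / n."""
    n = X.shape[0]
    return float(2.0 * np.abs(X.T @ Y).max() / n)


def make_tau_grid(X: np.ndarray, Y: np.ndarray, n_values: int = 20, ratio: float = 1000.0) -> np.ndarray:
    """Decreasing geometric grid from tau_max down to tau_max / ratio."""
    t_max = tau_max(X, Y)
    if t_max == 0:
        raise ValueError("X^T Y is identically zero; no informative tau grid")
    return np.geomspace(t_max, t_max / ratio, n_values)


def _soft_threshold(z: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)


def fit_l1l2(
    X: np.ndarray,
    Y: np.ndarray,
    tau: float,
    lambda_: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    beta0: np.ndarray | None = None,
    sigma: float | None = None,
    gene_ids: list[str] | None = None,
) -> ElasticNetModel:
    """Minimize the l1+l2 penalized least-squares objective.

    ``beta0`` warm-starts the iteration (useful along a tau path);
    ``sigma`` may pass a precomputed step constant (must satisfy
    sigma >= lambda + ||X^T X||_2/n). Stops when
    ||beta_{k+1} - beta_k|| <= tol * ||beta_k||; non-convergence sets
    ``converged=False`` rather than raising.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in X or Y")
    if tau < 0 or lambda_ < 0:
        raise ValueError("tau and lambda must be nonnegative")
    n, d = X.shape
    if sigma is None:
        sigma = lambda_ + gram_spectral_norm(X) / n
    if sigma <= 0:
        sigma = 1.0  # degenerate all-zero X

    beta = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    thr = tau / (2.0 * sigma)
    history = [objective(X, Y, beta, tau, lambda_)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad_step = beta * (sigma - lambda_) + (X.T @ (Y - X @ beta)) / n
        new = _soft_threshold(grad_step / sigma, thr)
        delta = np.linalg.norm(new - beta)
        prev_norm = np.linalg.norm(beta)
        beta = new
        history.append(objective(X, Y, beta, tau, lambda_))
        if delta <= tol * prev_norm or (prev_norm == 0.0 and delta == 0.0):
            converged = True
            break
    if not converged:
        logger.warning(
            "l1l2 solver did not converge in %d iterations (tau=%.3g, lambda=%.3g)",
            max_iter, tau, lambda_,
        )
    return ElasticNetModel(
        beta=beta,
        tau=float(tau),
        lambda_=float(lambda_),
        n_iter=n_iter,
        converged=converged,
        objective=history[-1],
        objective_history=np.asarray(history),
        gene_ids=gene_ids,
    )


def kkt_residual(X, Y, beta, tau, lambda_) -> float:
    """Maximum violation of the subgradient optimality conditions.

    At the optimum, g_j = (2/n) X_j^T (Y - X beta) - 2 lambda beta_j
    satisfies |g_j| <= tau where beta_j = 0 and g_j = tau sign(beta_j)
    elsewhere.
    """
    n = X.shape[0]
    g = 2.0 * (X.T @ (Y - X @ beta)) / n - 2.0 * lambda_ * beta
    zero = beta == 0
    res_zero = np.maximum(np.abs(g[zero]) - tau, 0.0)
    res_active = np.abs(g[~zero] - tau * np.sign(beta[~zero]))
    residuals = np.concatenate([res_zero, res_active])
    return float(residuals.max()) if residuals.size else 0.0


def refit_on_support(
    X: np.ndarray,
    Y: np.ndarray,
    support,
    lambda_refit: float,
    gene_ids: list[str] | None = None,
) -> ElasticNetModel:
    """Ridge refit restricted to the selected columns.

    Off-support weights are exactly 0. An empty support yields a
    majority-class fallback model (logged), not an exception.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, d = X.shape
    support = np.asarray(support, dtype=int)
    beta = np.zeros(d)
    if support.size == 0:
        majority = 1 if np.sum(Y > 0) >= np.sum(Y < 0) else -1
        logger.info("empty support: falling back to majority class %+d", majority)
        return ElasticNetModel(
            beta=beta,
            tau=0.0,
            lambda_=float(lambda_refit),
            n_iter=0,
            converged=True,
            objective=objective(X, Y, beta, 0.0, lambda_refit),
            gene_ids=gene_ids,
            fallback_label=majority,
        )
    Xs = X[:, support]
    A = Xs.T @ Xs / n + lambda_refit * np.eye(support.size)
    b = Xs.T @ Y / n
    beta[support] = np.linalg.solve(A, b)
    return ElasticNetModel(
        beta=beta,
        tau=0.0,
        lambda_=float(lambda_refit),
        n_iter=1,
        converged=True,
        objective=objective(X, Y, beta, 0.0, lambda_refit),
        gene_ids=gene_ids,
    )


def predict(model: ElasticNetModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (sign of the score; 0 -> +1 by convention) and raw scores."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.beta.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns, "
            f"model expects {model.beta.shape[0]}"
        )
    scores = X_new @ model.beta
    if model.fallback_label is not None and not model.beta.any():
        labels = np.full(X_new.shape[0], model.fallback_label, dtype=int)
        return labels, scores
    if np.any(scores == 0.0):
        logger.info("tied score(s) exactly 0 assigned to class +1 by convention")
    labels = np.where(scores < 0, -1, 1)
    return labels, scores
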