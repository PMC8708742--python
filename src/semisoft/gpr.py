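"""Gaussian-process regression used to bound the pseudo-label search.

Before pseudo labels are optimized, a GPR model fitted to the labeled set
provides a predictive mean and variance at every unlabeled input; the
two-sided normal confidence interval around the mean becomes the per-label
search box handed to the genetic algorithm.

The kernel is the squared exponential k(x, x') = s_f^2 exp(-||x-x'||^2 / (2 l^2))
with additive observation noise s_n^2.  Hyperparameters follow a fixed,
deterministic heuristic: lengthscale = median pairwise distance of the
training inputs, signal variance = var(y), noise variance = 0.1 var(y).
The predictive variance reported here includes the observation noise, since
the quantity being bracketed is a noisy label, not the latent function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GPRBoundModel:
    kernel_lengthscale: float
    kernel_variance: float
    noise_variance: float
    training_inputs: np.ndarray
    dual_coefficients: np.ndarray
    y_mean: float
    cho: tuple | None  # Cholesky factor of K + s_n^2 I; None for the prior-only fallback

    def kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        sq = cdist(np.atleast_2d(A), np.atleast_2d(B), metric="sqeuclidean")
        return self.kernel_variance * np.exp(-sq / (2.0 * self.kernel_lengthscale**2))

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance (noise included) at each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        prior_var = self.kernel_variance + self.noise_variance
        if self.cho is None:
            n = X.shape[0]
            return np.full(n, self.y_mean), np.full(n, prior_var)
        Ks = self.kernel(X, self.training_inputs)
        mean = self.y_mean + Ks @ self.dual_coefficients
        v = cho_solve(self.cho, Ks.T)
        var = prior_var - np.einsum("ij,ji->i", Ks, v)
        return mean, np.maximum(var, 0.0)


def _neg_log_marginal_likelihood(
    log_params: np.ndarray, sq: np.ndarray, y_c: np.ndarray
) -> float:
    ell, sf2, sn2 = np.exp(log_params)
    K = sf2 * np.exp(-sq / (2.0 * ell**2)) + sn2 * np.eye(len(y_c))
    try:
        c = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25
    alpha = cho_solve(c, y_c)
    return float(
        0.5 * y_c @ alpha + np.sum(np.log(np.diag(c[0]))) + 0.5 * len(y_c) * np.log(2 * np.pi)
    )


def fit_gpr(X: np.ndarray, y: np.ndarray, optimize: bool = False) -> GPRBoundModel:
    """Fit the squared-exponential GPR with heuristic hyperparameters.

    With ``optimize=True`` the heuristic values initialize a deterministic
    marginal-likelihood ascent (L-BFGS-B over the log hyperparameters),
    yielding calibrated predictive intervals instead of the fixed
    0.1-var(y) noise assumption.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("GPR needs at least two training samples")
    var_y = float(np.var(y))
    kernel_variance = var_y if var_y > 0 else 1.0
    noise_variance = 0.1 * var_y if var_y > 0 else 1e-6
    dists = pdist(X)
    median_dist = float(np.median(dists)) if dists.size else 0.0
    if median_dist <= 0.0:
        logger.warning("degenerate (constant) inputs; falling back to prior-only GPR")
        return GPRBoundModel(
            kernel_lengthscale=1.0,
            kernel_variance=kernel_variance,
            noise_variance=noise_variance,
            training_inputs=X,
            dual_coefficients=np.zeros(X.shape[0]),
            y_mean=float(np.mean(y)),
            cho=None,
        )
    y_mean = float(np.mean(y))
    sq = cdist(X, X, metric="sqeuclidean")
    lengthscale = median_dist
    if optimize:
        from scipy.optimize import minimize

        x0 = np.log([median_dist, kernel_variance, noise_variance])
        res = minimize(
            _neg_log_marginal_likelihood,
            x0,
            args=(sq, y - y_mean),
            method="L-BFGS-B",
            bounds=[(x0[0] - 5, x0[0] + 5), (x0[1] - 8, x0[1] + 8), (x0[2] - 12, x0[2] + 4)],
        )
        if res.success or res.fun < _neg_log_marginal_likelihood(x0, sq, y - y_mean):
            lengthscale, kernel_variance, noise_variance = np.exp(res.x)
    K = kernel_variance * np.exp(-sq / (2.0 * lengthscale**2))
    cho = cho_factor(K + noise_variance * np.eye(X.shape[0]), lower=True)
    alpha = cho_solve(cho, y - y_mean)
    return GPRBoundModel(
        kernel_lengthscale=median_dist,
        kernel_variance=kernel_variance,
        noise_variance=noise_variance,
        training_inputs=X,
        dual_coefficients=alpha,
        y_mean=y_mean,
        cho=cho,
    )


def pseudo_label_bounds(
    gpr: GPRBoundModel, X_u: np.ndarray, ci_level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point search interval [mean - z sd, mean + z sd] at the given level.

    A zero predictive sd would collapse the interval, so degenerate bounds
    are widened by eps = 1e-6 * max(1, |mean|).
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    z = norm.ppf(0.5 + ci_level / 2.0)
    mean, var = gpr.predict(X_u)
    sd = np.sqrt(var)
    half = z * sd
    eps = 1e-6 * np.maximum(1.0, np.abs(mean))
    half = np.where(half <= 0.0, eps, half)
    return mean - half, mean + half
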