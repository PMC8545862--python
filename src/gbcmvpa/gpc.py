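"""Binary Gaussian process classification with the Laplace approximation,
operating on a precomputed (linear) kernel.

Model: latent GP with covariance k(x, x') = <x, x'> + bias_variance (linear
covariance plus bias, zero mean) and a logistic likelihood.  The posterior
over latent values is approximated at its mode by a Gaussian (Laplace);
mode finding uses the standard stabilized Newton iteration, and predictive
class probabilities use the MacKay approximation to the logistic-Gaussian
integral, sigma(mu / sqrt(1 + pi * var / 8)).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

__all__ = ["LaplaceKernelGPC"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LaplaceKernelGPC:
    """Laplace-approximate GP classifier on a precomputed kernel matrix.

    Parameters
    ----------
    bias_variance : float
        Constant added to every kernel entry (the "+ c" of a linear kernel
        with bias); plays the role of a soft intercept.
    jitter : float
        Diagonal regularization for numerical stability.
    max_iter, tol : Newton iteration controls.
    """

    def __init__(self, bias_variance: float = 1.0, jitter: float = 1e-8,
                 max_iter: int = 100, tol: float = 1e-9) -> None:
        self.bias_variance = bias_variance
        self.jitter = jitter
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, K_train: np.ndarray, y: np.ndarray) -> "LaplaceKernelGPC":
        """Fit with K_train an (n, n) Gram matrix and y in {-1, +1}."""
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("labels must be coded -1/+1")
        if len(set(y)) < 2:
            raise ValueError("training set must contain both classes")
        n = len(y)
        K = np.asarray(K_train, dtype=float) + self.bias_variance
        K = K + self.jitter * np.eye(n)

        f = np.zeros(n)
        obj_prev = -np.inf
        t = (y + 1.0) / 2.0
        for _ in range(self.max_iter):
            pi = _sigmoid(f)
            W = pi * (1.0 - pi)
            sw = np.sqrt(W)
            B = np.eye(n) + sw[:, None] * K * sw[None, :]
            L = cholesky(B, lower=True)
            b = W * f + (t - pi)
            a = b - sw * cho_solve((L, True), sw * (K @ b))
            f = K @ a
            # log p(y|f) with logistic likelihood, numerically safe
            loglik = -np.logaddexp(0.0, -y * f).sum()
            obj = -0.5 * a @ f + loglik
            if abs(obj - obj_prev) < self.tol:
                break
            obj_prev = obj

        pi = _sigmoid(f)
        self._alpha = t - pi               # gradient at the mode
        self._sqrt_w = np.sqrt(pi * (1.0 - pi))
        B = np.eye(n) + self._sqrt_w[:, None] * K * self._sqrt_w[None, :]
        self._L = cholesky(B, lower=True)
        self._f_mode = f
        self.log_marginal_likelihood_ = float(
            -0.5 * self._alpha @ f
            - np.logaddexp(0.0, -y * f).sum()
            - np.log(np.diag(self._L)).sum()
        )
        return self

    @property
    def alpha_(self) -> np.ndarray:
        """Dual coefficients: the latent predictive mean at x* is
        k(x*, X) @ alpha_ (kernel including the bias term)."""
        return self._alpha

    def latent_mean(self, K_star: np.ndarray) -> np.ndarray:
        """Predictive latent mean for test rows; K_star is (m, n) against
        the training set, without the bias term."""
        return (np.asarray(K_star, dtype=float) + self.bias_variance) @ self._alpha

    def predict_proba(self, K_star: np.ndarray, k_star_diag: np.ndarray) -> np.ndarray:
        """Probability of the +1 class.

        k_star_diag holds k(x*, x*) for each test row (without bias).
        """
        Ks = np.asarray(K_star, dtype=float) + self.bias_variance
        mu = Ks @ self._alpha
        v = solve_triangular(self._L, self._sqrt_w[:, None] * Ks.T, lower=True)
        var = np.asarray(k_star_diag, dtype=float) + self.bias_variance + self.jitter \
            - np.sum(v ** 2, axis=0)
        var = np.maximum(var, 0.0)
        kappa = 1.0 / np.sqrt(1.0 + np.pi * var / 8.0)
        return _sigmoid(kappa * mu)
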