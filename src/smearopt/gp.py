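"""Gaussian-process surrogate with a Matérn 5/2 kernel.

The surrogate models the (expensive) objective over the unit hypercube.  It
is a zero-mean GP on standardized targets with automatic-relevance-
determination (per-dimension) length scales.  Kernel hyperparameters —
signal variance, length scales and observation noise — are chosen by
maximizing the log marginal likelihood with a multi-start quasi-Newton
search inside fixed box bounds.

All linear algebra goes through a single Cholesky factor of
``K + noise * I``; a jitter ladder enlarges the noise term until the
factorization succeeds, and any jitter actually used is folded into the
stored noise variance so the factor always reconstructs the stored kernel
matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = ["matern52", "GPModel", "GPFitConfig", "gp_fit", "gp_predict"]

_SQRT5 = np.sqrt(5.0)


def matern52(r, length_scale: float, signal_variance: float):
    """Matérn 5/2 covariance as a function of Euclidean distance ``r``.

    k(r) = sigma_f^2 * (1 + sqrt(5) r / l + 5 r^2 / (3 l^2)) exp(-sqrt(5) r / l)

    ``r`` may be a scalar or array of non-negative distances.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    if signal_variance <= 0:
        raise ValueError("signal_variance must be positive")
    s = np.asarray(r, dtype=float) / length_scale
    out = signal_variance * (1.0 + _SQRT5 * s + 5.0 * s**2 / 3.0) * np.exp(-_SQRT5 * s)
    return out if np.ndim(r) else float(out)


def _scaled_sq_dists(A: np.ndarray, B: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Per-dimension squared distances scaled by length scales, summed."""
    d = A[:, None, :] - B[None, :, :]
    return np.sum((d / ls[None, None, :]) ** 2, axis=2)


def _kernel_matrix(A, B, ls, sf2):
    r = np.sqrt(np.maximum(_scaled_sq_dists(A, B, ls), 0.0))
    return sf2 * (1.0 + _SQRT5 * r + 5.0 * r**2 / 3.0) * np.exp(-_SQRT5 * r)


@dataclass
class GPFitConfig:
    """Controls for the marginal-likelihood hyperparameter search."""

    n_restarts: int = 8
    lengthscale_bounds: tuple[float, float] = (1e-3, 10.0)
    signal_bounds: tuple[float, float] = (1e-6, 10.0)  # on standardized y
    noise_bounds: tuple[float, float] = (1e-8, 1.0)  # on standardized y
    maxiter: int = 100
    jitter_ladder: tuple[float, ...] = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


@dataclass
class GPModel:
    """Fitted surrogate: design, targets and factorized covariance."""

    X: np.ndarray  # (n, d) unit-cube design
    y: np.ndarray  # (n,) objectives, natural scale
    y_mean: float
    y_sd: float
    signal_variance: float
    length_scales: np.ndarray  # (d,)
    noise_variance: float
    chol: np.ndarray  # lower factor of K + noise I (standardized scale)
    alpha: np.ndarray  # (K + noise I)^{-1} y_std

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dimension(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_hyperparameters(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        signal_variance: float,
        length_scales,
        noise_variance: float,
        standardize: bool = True,
        jitter_ladder: tuple[float, ...] = GPFitConfig.jitter_ladder,
    ) -> "GPModel":
        """Build a model at fixed kernel hyperparameters (no fitting)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        ls = np.broadcast_to(
            np.asarray(length_scales, dtype=float), (X.shape[1],)
        ).copy()
        if standardize:
            y_mean = float(np.mean(y))
            y_sd = float(np.std(y))
            if y_sd < 1e-12:
                y_sd = 1.0
        else:
            y_mean, y_sd = 0.0, 1.0
        y_std = (y - y_mean) / y_sd
        K = _kernel_matrix(X, X, ls, signal_variance)
        L, eff_noise = _factorize(K, noise_variance, jitter_ladder)
        alpha = cho_solve((L, True), y_std)
        return cls(
            X=X,
            y=y,
            y_mean=y_mean,
            y_sd=y_sd,
            signal_variance=float(signal_variance),
            length_scales=ls,
            noise_variance=eff_noise,
            chol=L,
            alpha=alpha,
        )

    def predict(self, X_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at query points.

        Accepts a single ``(d,)`` vector or an ``(m, d)`` array; returns
        arrays of means and sds on the natural objective scale.
        """
        Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
        if Xq.shape[1] != self.dimension:
            raise ValueError(
                f"query dimension {Xq.shape[1]} != model dimension {self.dimension}"
            )
        Ks = _kernel_matrix(Xq, self.X, self.length_scales, self.signal_variance)
        mean_std = Ks @ self.alpha
        V = solve_triangular(self.chol, Ks.T, lower=True)
        var = self.signal_variance - np.sum(V**2, axis=0)
        var = np.clip(var, 0.0, None)
        mean = self.y_mean + self.y_sd * mean_std
        sd = self.y_sd * np.sqrt(var)
        return mean, sd


def _factorize(K: np.ndarray, noise: float, ladder) -> tuple[np.ndarray, float]:
    """Cholesky of K + (noise + jitter) I, escalating jitter until success."""
    n = K.shape[0]
    for jitter in ladder:
        try:
            L = cholesky(K + (noise + jitter) * np.eye(n), lower=True)
            return L, noise + jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "kernel matrix not positive definite even at maximum jitter"
    )


def _nll_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log marginal likelihood and gradient wrt log-parameters.

    ``theta`` = (log l_1..d, log sigma_f^2, log sigma_n^2).
    """
    n, d = X.shape
    ls = np.exp(theta[:d])
    sf2 = np.exp(theta[d])
    sn2 = np.exp(theta[d + 1])

    diff = X[:, None, :] - X[None, :, :]
    D = diff**2  # (n, n, d)
    r2 = np.sum(D / ls[None, None, :] ** 2, axis=2)
    r = np.sqrt(np.maximum(r2, 0.0))
    expterm = np.exp(-_SQRT5 * r)
    A = (1.0 + _SQRT5 * r + 5.0 * r2 / 3.0) * expterm
    K = sf2 * A + sn2 * np.eye(n)

    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((L, True), y)
    nll = (
        0.5 * float(y @ alpha)
        + float(np.sum(np.log(np.diag(L))))
        + 0.5 * n * np.log(2.0 * np.pi)
    )

    Kinv = cho_solve((L, True), np.eye(n))
    W = Kinv - np.outer(alpha, alpha)  # dNLL/dK applied via 0.5 * sum(W * dK)

    grad = np.empty_like(theta)
    # d/d log l_k : sigma_f^2 * (5/3)(1 + sqrt5 r) e^{-sqrt5 r} * D_k / l_k^2
    B = sf2 * (5.0 / 3.0) * (1.0 + _SQRT5 * r) * expterm
    for k in range(d):
        dK = B * (D[:, :, k] / ls[k] ** 2)
        grad[k] = 0.5 * np.sum(W * dK)
    grad[d] = 0.5 * np.sum(W * (sf2 * A))
    grad[d + 1] = 0.5 * np.trace(W) * sn2
    return nll, grad


def gp_fit(
    X: np.ndarray,
    y: np.ndarray,
    config: GPFitConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> GPModel:
    """Fit the surrogate by maximizing the log marginal likelihood.

    Targets are standardized internally; hyperparameters are searched in
    log space with ``config.n_restarts`` L-BFGS-B starts inside the box
    bounds (first start at a fixed moderate point, the rest drawn
    log-uniformly by ``rng``).
    """
    config = config or GPFitConfig()
    rng = np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 2:
        raise ValueError("gp_fit requires at least 2 observations")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("gp_fit requires finite inputs")

    y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    if y_sd < 1e-12:
        y_sd = 1.0
    y_std = (y - y_mean) / y_sd

    lb = np.log(
        np.array([config.lengthscale_bounds[0]] * d
                 + [config.signal_bounds[0], config.noise_bounds[0]])
    )
    ub = np.log(
        np.array([config.lengthscale_bounds[1]] * d
                 + [config.signal_bounds[1], config.noise_bounds[1]])
    )
    bounds = list(zip(lb, ub))

    starts = [np.log(np.array([0.5] * d + [1.0, 1e-3]))]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(lb + rng.random(d + 2) * (ub - lb))

    best_theta, best_nll = None, np.inf
    for theta0 in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(theta0, lb, ub),
            args=(X, y_std),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        if res.fun < best_nll:
            best_nll, best_theta = res.fun, res.x

    ls = np.exp(best_theta[:d])
    sf2 = float(np.exp(best_theta[d]))
    sn2 = float(np.exp(best_theta[d + 1]))

    model = GPModel.from_hyperparameters(
        X,
        y,
        signal_variance=sf2,
        length_scales=ls,
        noise_variance=sn2,
        standardize=True,
        jitter_ladder=config.jitter_ladder,
    )
    return model


def gp_predict(model: GPModel, x: np.ndarray) -> tuple[float, float]:
    """Posterior mean and sd at a single unit-cube point."""
    mean, sd = model.predict(np.asarray(x, dtype=float))
    return float(mean[0]), float(sd[0])
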