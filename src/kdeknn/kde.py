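"""Multivariate Gaussian kernel density estimation.

The estimator is the plain finite mixture

    p(x) = 1/(L h^d) * sum_i K((x - x_i) / h),
    K(u) = (2*pi)^(-d/2) * exp(-||u||^2 / 2),

with a single scalar bandwidth ``h`` chosen by Scott's rule
``h = L^(-1/(d+4))``.  The isotropic kernel is the default because generation
happens on z-scored features, where all coordinates share a scale.  A
``covariance_scaled`` mode replaces the identity kernel shape with the
empirical covariance of the support (the convention of scipy's
``gaussian_kde``), useful when features are correlated.

Sampling is exact mixture sampling: pick a support point uniformly, add
kernel-shaped noise.  Density evaluation uses log-sum-exp, so queries far from
all support return finite log-densities instead of underflowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .errors import DataError, FitError

__all__ = ["KDEModel", "scott_bandwidth", "fit_kde", "log_density", "sample_kde"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def scott_bandwidth(L: int, d: int) -> float:
    """Scott's rule bandwidth for L support points in d dimensions.

    Returns ``L**(-1/(d+4))``, the standard plug-in rate for Gaussian kernels;
    on standardized data the per-feature scale factor is 1.
    """
    if L < 1:
        raise DataError("empty support: L must be >= 1")
    if d < 1:
        raise ValueError("d must be >= 1")
    return float(L) ** (-1.0 / (d + 4))


@dataclass
class KDEModel:
    """A fitted kernel density: support points, bandwidth and kernel shape.

    ``chol`` is the lower Cholesky factor of the kernel shape matrix
    (covariance_scaled mode only); ``log_norm`` caches the log of the kernel
    normalizing constant including the h and |Sigma| terms.
    """

    support: np.ndarray
    h: float
    kernel_mode: str = "isotropic"
    covariance: Optional[np.ndarray] = None
    chol: Optional[np.ndarray] = None

    @property
    def L(self) -> int:
        return self.support.shape[0]

    @property
    def d(self) -> int:
        return self.support.shape[1]


def fit_kde(
    points: np.ndarray,
    bandwidth_override: Optional[float] = None,
    kernel_mode: str = "isotropic",
) -> KDEModel:
    """Fit a Gaussian KDE on `points` (L x d), bandwidth by Scott unless given.

    In ``covariance_scaled`` mode the empirical covariance of the support is
    regularized by ``eps*I`` with ``eps = 1e-8 * trace/d`` and Cholesky
    factored; degenerate support (e.g. identical points) therefore raises
    :class:`FitError` in that mode but is valid in isotropic mode.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise DataError("support contains non-finite values")
    L, d = points.shape
    if L < 1:
        raise DataError("empty support")
    if kernel_mode not in ("isotropic", "covariance_scaled"):
        raise ValueError(f"unknown kernel_mode {kernel_mode!r}")
    if bandwidth_override is not None:
        if bandwidth_override <= 0:
            raise ValueError("bandwidth must be positive")
        h = float(bandwidth_override)
    else:
        h = scott_bandwidth(L, d)

    cov = chol = None
    if kernel_mode == "covariance_scaled":
        if L < 2:
            raise FitError("covariance_scaled mode needs at least 2 points")
        cov = np.cov(points, rowvar=False, ddof=1).reshape(d, d)
        eps = 1e-8 * np.trace(cov) / d
        cov = cov + eps * np.eye(d)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "singular support covariance after regularization"
            ) from exc
    return KDEModel(points, h, kernel_mode, cov, chol)


def log_density(model: KDEModel, query: np.ndarray) -> np.ndarray:
    """Evaluate log p(x) at each row of `query` (Q x d), numerically stable."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if query.shape[1] != model.d:
        raise DataError(
            f"query dimension {query.shape[1]} != model dimension {model.d}"
        )
    h, d, L = model.h, model.d, model.L
    if model.kernel_mode == "isotropic":
        sq = cdist(query, model.support, metric="sqeuclidean")
        log_norm = -np.log(L) - d * np.log(h) - 0.5 * d * _LOG_2PI
    else:
        # whiten with the kernel Cholesky factor, then it is isotropic
        from scipy.linalg import solve_triangular

        qw = solve_triangular(model.chol, query.T, lower=True).T
        sw = solve_triangular(model.chol, model.support.T, lower=True).T
        sq = cdist(qw, sw, metric="sqeuclidean")
        logdet = 2.0 * np.sum(np.log(np.diag(model.chol)))
        log_norm = (-np.log(L) - d * np.log(h) - 0.5 * logdet
                    - 0.5 * d * _LOG_2PI)
    return logsumexp(-0.5 * sq / (h * h), axis=1) + log_norm


def sample_kde(
    model: KDEModel,
    n: int,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Draw n samples: uniform support point + bandwidth-scaled Gaussian noise.

    `seed` may be an integer or an existing :class:`numpy.random.Generator`
    (which is advanced in place).  The component indices are drawn before the
    noise, so streams are reproducible.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, model.d))
    idx = rng.integers(model.L, size=n)
    z = rng.standard_normal((n, model.d))
    if model.kernel_mode == "isotropic":
        noise = model.h * z
    else:
        noise = model.h * (z @ model.chol.T)
    return model.support[idx] + noise
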