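"""Synthetic clinical-style fixtures for end-to-end testing.

Real ICU sepsis cohorts are not redistributable, so this module generates
datasets that emulate their statistical shape: ~27 continuous features,
~1275 records with heavy class imbalance (979 controls vs 296 cases),
class-conditional mean shift, exchangeable feature correlation and missing
values (MCAR).  Class-conditional multivariate Gaussians are used on purpose:
every downstream moment has a closed-form target, so tests can assert
convergence instead of eyeballing.

What this does NOT emulate: skewed/heavy-tailed lab-value marginals, mixed
discrete/continuous features, informative missingness, and temporal
structure.  Tests passing on these fixtures demonstrate correctness of the
machinery, not clinical validity on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .datasets import TabularDataset
from .errors import DataError

__all__ = ["FixtureSpec", "make_clinical_fixture", "make_shifted_pair"]


@dataclass
class FixtureSpec:
    """Generative parameters for a clinical-style fixture.

    Defaults mirror the shape of a real ICU cohort: 979 negatives (no sepsis),
    296 positives (sepsis), 27 features, a moderate per-feature class effect,
    mild exchangeable correlation and 5% missingness.
    """

    n_negative: int = 979
    n_positive: int = 296
    d: int = 27
    effect: Union[float, np.ndarray] = 0.3
    correlation: Union[float, np.ndarray] = 0.2
    noise_scale: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0

    def covariance(self) -> np.ndarray:
        """Feature covariance implied by the spec; must be positive definite."""
        if np.isscalar(self.correlation):
            rho = float(self.correlation)
            if not 0.0 <= rho < 1.0:
                raise DataError("exchangeable correlation must be in [0, 1)")
            corr = np.full((self.d, self.d), rho)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (self.d, self.d):
                raise DataError("correlation matrix shape must be (d, d)")
            if np.linalg.eigvalsh(corr).min() <= 0:
                raise DataError("correlation matrix must be positive definite")
        return (self.noise_scale**2) * corr

    def effect_vector(self) -> np.ndarray:
        e = np.asarray(self.effect, dtype=float)
        return np.full(self.d, float(e)) if e.ndim == 0 else e

    def validate(self) -> None:
        if self.n_negative < 0 or self.n_positive < 0:
            raise DataError("class counts must be >= 0")
        if self.d < 1:
            raise DataError("d must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataError("missing_rate must be in [0, 1)")
        if self.effect_vector().shape != (self.d,):
            raise DataError("effect vector length must equal d")
        self.covariance()


def _draw(
    spec: FixtureSpec,
    rng: np.random.Generator,
    mean_offset: np.ndarray,
) -> TabularDataset:
    cov = spec.covariance()
    mu0 = np.zeros(spec.d) + mean_offset
    mu1 = mu0 + spec.effect_vector()
    x_neg = rng.multivariate_normal(mu0, cov, size=spec.n_negative,
                                    method="cholesky")
    x_pos = rng.multivariate_normal(mu1, cov, size=spec.n_positive,
                                    method="cholesky")
    values = np.concatenate([x_neg, x_pos])
    labels = np.concatenate([
        np.zeros(spec.n_negative, dtype=int),
        np.ones(spec.n_positive, dtype=int),
    ])
    order = rng.permutation(values.shape[0])
    values, labels = values[order], labels[order]
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan
    names = [f"feat_{j:02d}" for j in range(spec.d)]
    return TabularDataset(values, labels, names)


def make_clinical_fixture(spec: Optional[FixtureSpec] = None) -> TabularDataset:
    """Draw one cohort from the class-conditional Gaussian family."""
    spec = spec or FixtureSpec()
    spec.validate()
    return _draw(spec, np.random.default_rng(spec.seed), np.zeros(spec.d))


def make_shifted_pair(
    spec: Optional[FixtureSpec] = None,
    shift: Union[float, np.ndarray] = 0.0,
) -> tuple[TabularDataset, TabularDataset]:
    """Two cohorts from the same family, the second with shifted means.

    Emulates a training hospital vs an external-validation hospital whose
    feature distributions drifted; exercises the dataset-shift screen and
    external-validation code paths.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    shift = np.asarray(shift, dtype=float)
    shift_vec = np.full(spec.d, float(shift)) if shift.ndim == 0 else shift
    if shift_vec.shape != (spec.d,):
        raise DataError("shift vector length must equal d")
    ss = np.random.SeedSequence(spec.seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    cohort_a = _draw(spec, rng_a, np.zeros(spec.d))
    cohort_b = _draw(spec, rng_b, shift_vec)
    return cohort_a, cohort_b
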