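"""Statistical-similarity metrics between real and synthetic cohorts.

Four views, each answering a different question:

* per-feature two-sample Kolmogorov-Smirnov battery — do the one-dimensional
  marginals differ? (summarized by the mean p-value across features);
* density & coverage (k-NN ball counts, k=5) — fidelity and diversity of the
  synthetic cloud around the real points; density can exceed 1, coverage is a
  proportion;
* dimension-wise moment comparison — per-feature means/variances with 95%
  normal-approximation confidence intervals, for agreement plots;
* dataset-shift report — per-feature two-sided Mann-Whitney U with Bonferroni
  correction, the standard screen for distribution shift between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import DataError

__all__ = [
    "KSBatteryResult",
    "ks_battery",
    "density_coverage",
    "moment_comparison",
    "shift_report",
]

SIGNIFICANCE_LEVEL = 0.01  # convention for flagging shifted features


@dataclass
class KSBatteryResult:
    table: pd.DataFrame  # feature, statistic, p_value

    @property
    def mean_p_value(self) -> float:
        return float(self.table["p_value"].mean())


def ks_battery(
    real: np.ndarray,
    synthetic: np.ndarray,
    feature_names: list[str] | None = None,
) -> KSBatteryResult:
    """Two-sample KS test per feature (asymptotic p-values)."""
    real = np.atleast_2d(np.asarray(real, dtype=float))
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=float))
    if real.shape[1] != synthetic.shape[1]:
        raise DataError("real and synthetic have different feature counts")
    if real.shape[0] < 2 or synthetic.shape[0] < 2:
        raise DataError("need >= 2 rows per set for the KS test")
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(real.shape[1])]
    rows = []
    for j, name in enumerate(feature_names):
        res = stats.ks_2samp(real[:, j], synthetic[:, j], method="asymp")
        rows.append((name, float(res.statistic), float(res.pvalue)))
    return KSBatteryResult(
        pd.DataFrame(rows, columns=["feature", "statistic", "p_value"])
    )


def density_coverage(
    real: np.ndarray,
    synthetic: np.ndarray,
    k: int = 5,
) -> tuple[float, float]:
    """k-NN density and coverage of `synthetic` with respect to `real`.

    With r_i the distance from real point i to its k-th nearest *other* real
    point (closed balls):

    * density  = (1/(k*Q)) * #{(i, j): ||y_j - x_i|| <= r_i} — how densely
      synthetic points populate real neighborhoods; unbounded above;
    * coverage = fraction of real points whose ball contains at least one
      synthetic point — diversity; in [0, 1].
    """
    real = np.atleast_2d(np.asarray(real, dtype=float))
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=float))
    n, q = real.shape[0], synthetic.shape[0]
    if n <= k:
        raise DataError(f"need N > k (N={n}, k={k})")
    if np.isnan(real).any() or np.isnan(synthetic).any():
        raise DataError("missing values; preprocess first")
    d_rr = cdist(real, real)
    np.fill_diagonal(d_rr, np.inf)
    # k-th nearest other real point: index k-1 of the sorted row
    radii = np.partition(d_rr, k - 1, axis=1)[:, k - 1]
    d_rs = cdist(real, synthetic)
    inside = d_rs <= radii[:, None]
    density = float(inside.sum()) / (k * q)
    coverage = float(inside.any(axis=1).mean())
    return density, coverage


def moment_comparison(
    real: np.ndarray,
    synthetic: np.ndarray,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature mean/variance for both sets with 95% CIs on the means."""
    real = np.atleast_2d(np.asarray(real, dtype=float))
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=float))
    if real.shape[0] < 2 or synthetic.shape[0] < 2:
        raise DataError("need >= 2 rows per set")
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(real.shape[1])]

    def _stats(x: np.ndarray, prefix: str) -> dict:
        n = x.shape[0]
        s = x.std(axis=0, ddof=1)
        return {
            f"{prefix}_mean": x.mean(axis=0),
            f"{prefix}_var": s**2,
            f"{prefix}_ci_halfwidth": 1.96 * s / np.sqrt(n),
        }

    out = {"feature": feature_names}
    out.update(_stats(real, "real"))
    out.update(_stats(synthetic, "synthetic"))
    return pd.DataFrame(out)


def shift_report(
    cohort_a: np.ndarray,
    cohort_b: np.ndarray,
    feature_names: list[str] | None = None,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney U shift screen with Bonferroni correction.

    Missing cells are dropped per feature.  The reported U is min(U1, U2); the
    two-sided p-value uses the tie-corrected normal approximation with
    continuity correction.  Adjusted p = min(1, d * p); a feature is flagged
    when the adjusted p falls below `alpha`.
    """
    cohort_a = np.atleast_2d(np.asarray(cohort_a, dtype=float))
    cohort_b = np.atleast_2d(np.asarray(cohort_b, dtype=float))
    if cohort_a.shape[1] != cohort_b.shape[1]:
        raise DataError("cohorts have different feature counts")
    d = cohort_a.shape[1]
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(d)]
    rows = []
    for j, name in enumerate(feature_names):
        a = cohort_a[:, j]
        b = cohort_b[:, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            raise DataError(f"feature {name!r} empty in one cohort")
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        u1 = float(res.statistic)
        u = min(u1, a.size * b.size - u1)
        p = float(res.pvalue)
        p_adj = min(1.0, d * p)
        rows.append((name, u, p, p_adj, p_adj < alpha))
    return pd.DataFrame(
        rows, columns=["feature", "U", "p_value", "p_adjusted", "significant"]
    )
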