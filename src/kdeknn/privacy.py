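"""Distance-to-Closest-Record (DCR) privacy metrics.

DCR is the Euclidean distance from a record to its nearest record in a
reference set.  Two flavours are needed:

* real vs real — for each real record, the nearest *other* real record
  (self excluded); the mean of these nearest-neighbor distances is the
  reference sigma used as the minimum acceptable distance between synthetic
  and real records;
* synthetic vs real — for each synthetic record, the nearest real record
  (no exclusion: a synthetic copy of a real record has DCR 0).

Distances are computed in the standardized feature space where generation
happens; a mean distance across raw clinical units would be meaningless.
Search is exact, in blocks, so memory stays bounded for a few thousand rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError

__all__ = ["DCRReport", "dcr_real_real", "dcr_synthetic", "dcr_distribution"]

_BLOCK = 512


@dataclass
class DCRReport:
    """Per-record minimum distances plus summary statistics."""

    distances: np.ndarray
    threshold: Optional[float] = None

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def n_below_threshold(self) -> int:
        if self.threshold is None:
            return 0
        return int((self.distances < self.threshold).sum())


def _min_dist_blockwise(a: np.ndarray, b: np.ndarray, exclude_self: bool) -> np.ndarray:
    """min_j ||a_i - b_j|| for each row i; optionally skip j == i (a is b)."""
    out = np.empty(a.shape[0])
    for start in range(0, a.shape[0], _BLOCK):
        stop = min(start + _BLOCK, a.shape[0])
        d = cdist(a[start:stop], b)
        if exclude_self:
            rows = np.arange(start, stop)
            d[rows - start, rows] = np.inf
        out[start:stop] = d.min(axis=1)
    return out


def dcr_real_real(X: np.ndarray, threshold: Optional[float] = None) -> DCRReport:
    """Nearest-other-record distance for each row of X; mean is sigma.

    Duplicated records legitimately give distance 0 — the self-exclusion is by
    row index, not by value.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise DataError("need at least 2 records for real-vs-real DCR")
    if np.isnan(X).any():
        raise DataError("missing values; preprocess before computing DCR")
    return DCRReport(_min_dist_blockwise(X, X, exclude_self=True), threshold)


def dcr_synthetic(
    S: np.ndarray,
    X: np.ndarray,
    threshold: Optional[float] = None,
) -> DCRReport:
    """Distance from each synthetic row of S to its closest real record in X."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1 or S.shape[0] < 1:
        raise DataError("both synthetic and real sets must be non-empty")
    if S.shape[1] != X.shape[1]:
        raise DataError(
            f"dimension mismatch: synthetic d={S.shape[1]}, real d={X.shape[1]}"
        )
    return DCRReport(_min_dist_blockwise(S, X, exclude_self=False), threshold)


def dcr_distribution(report: DCRReport, bins: int = 30):
    """Normalized histogram (area 1) of the per-record DCR values.

    Returns ``(densities, bin_edges)`` as :func:`numpy.histogram` does with
    ``density=True``.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if report.distances.size == 0:
        raise DataError("empty DCR report")
    return np.histogram(report.distances, bins=bins, density=True)
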