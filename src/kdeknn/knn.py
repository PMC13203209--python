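"""K-nearest-neighbor utility validator.

A deliberately simple lazy learner: the reference set is stored verbatim and a
query is classified by an unweighted majority vote among its k nearest
reference points (Euclidean distance).  It acts as the quality gate of the
generator — a synthetic candidate whose predicted class differs from the class
it was sampled for is discarded as unusable.

Tie handling is fixed so predictions are fully deterministic:

* neighbor ties (equal distances) are broken by reference index (stable sort
  on distance, lowest index first);
* vote ties (possible for even k) fall back to the label of the single
  nearest neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import TabularDataset
from .errors import DataError, FitError

__all__ = ["KNNModel", "fit_knn", "predict", "validate_candidates"]


@dataclass
class KNNModel:
    reference: np.ndarray
    labels: np.ndarray
    k: int


def fit_knn(train: TabularDataset, k: int = 5) -> KNNModel:
    """Store the (preprocessed) training set as the reference set.

    Requires 1 <= k <= N, both classes present and no missing cells.
    """
    x, y = train.values, train.labels
    if np.isnan(x).any():
        raise DataError("reference set contains missing values; preprocess first")
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= N={n}")
    if np.unique(y).size < 2:
        raise FitError("reference set contains a single class")
    return KNNModel(x.copy(), y.copy(), int(k))


def predict(model: KNNModel, query: np.ndarray) -> np.ndarray:
    """Majority-vote class for each row of `query` (Q x d)."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if query.shape[1] != model.reference.shape[1]:
        raise DataError(
            f"query dimension {query.shape[1]} != reference dimension "
            f"{model.reference.shape[1]}"
        )
    dist = cdist(query, model.reference)
    order = np.argsort(dist, axis=1, kind="stable")[:, : model.k]
    votes = model.labels[order]
    pos = votes.sum(axis=1)
    out = np.where(pos * 2 > model.k, 1, 0)
    tie = pos * 2 == model.k
    if tie.any():
        out[tie] = votes[tie, 0]  # nearest neighbor decides vote ties
    return out.astype(int)


def validate_candidates(
    model: KNNModel,
    candidates: np.ndarray,
    intended_label: int,
) -> np.ndarray:
    """Boolean mask: True where the validator agrees with the intended class."""
    return predict(model, candidates) == int(intended_label)
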