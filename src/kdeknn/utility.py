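"""Train-on-synthetic / test-on-real (TSTR) utility evaluation.

A classifier's usefulness is measured by the AUC it reaches on held-out real
data after training on real rows, synthetic rows, or a mix.  The AUC here is
the rank statistic (Mann-Whitney identity): the probability that a random
positive case outscores a random negative one, ties counted 1/2 — computed
from ranks, not from a plotted curve.

Classifiers plug in through a minimal contract (`fit` + `score`); the package
ships one dependency-light reference model, nearest-centroid on standardized
features, so the harness is fully testable on its own.  Off-the-shelf models
(random forests, SVMs, boosted trees) attach through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import TabularDataset
from .errors import DataError

__all__ = [
    "auc_score",
    "Classifier",
    "NearestCentroidClassifier",
    "UtilityResult",
    "evaluate_tstr",
    "summarize_results",
]


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity.

    AUC = P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg),
    computed as (rank-sum of positives - n_pos(n_pos+1)/2) / (n_pos * n_neg)
    with average ranks, which counts ties as 1/2 exactly.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise DataError("labels and scores must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


@runtime_checkable
class Classifier(Protocol):
    """Minimal contract: fit on (X, y), then score rows (higher = positive)."""

    name: str

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None: ...

    def score(self, features: np.ndarray) -> np.ndarray: ...


class NearestCentroidClassifier:
    """Reference classifier: signed distance difference to class centroids.

    score(x) = ||x - centroid_neg|| - ||x - centroid_pos||, so larger scores
    mean closer to the positive class.  Linear decision boundary, no
    hyperparameters — a minimal but honest baseline on standardized features.
    """

    name = "nearest_centroid"

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None:
        labels = np.asarray(labels).astype(int)
        if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
            raise DataError("both classes required to fit")
        self.centroid_pos_ = features[labels == 1].mean(axis=0)
        self.centroid_neg_ = features[labels == 0].mean(axis=0)

    def score(self, features: np.ndarray) -> np.ndarray:
        d_pos = np.linalg.norm(features - self.centroid_pos_, axis=1)
        d_neg = np.linalg.norm(features - self.centroid_neg_, axis=1)
        return d_neg - d_pos


@dataclass
class UtilityResult:
    """One AUC cell: classifier x synthetic fraction x replicate."""

    classifier: str
    synthetic_fraction: float
    replicate: int
    seed: int
    auc: float


def _stratified_subsample(
    data: TabularDataset, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample n rows without replacement, preserving the class ratio."""
    if n > data.n:
        raise DataError(f"requested {n} rows from a set of {data.n}")
    idx_pos = np.flatnonzero(data.labels == 1)
    idx_neg = np.flatnonzero(data.labels == 0)
    n_pos = int(round(n * idx_pos.size / data.n))
    n_pos = min(max(n_pos, 0), idx_pos.size)
    n_neg = n - n_pos
    if n_neg > idx_neg.size:  # rounding pushed too far, rebalance
        n_neg = idx_neg.size
        n_pos = n - n_neg
    take = np.concatenate([
        rng.choice(idx_pos, size=n_pos, replace=False),
        rng.choice(idx_neg, size=n_neg, replace=False),
    ])
    return data.values[take], data.labels[take]


def evaluate_tstr(
    train_real: TabularDataset,
    synthetic: TabularDataset,
    test: TabularDataset,
    classifiers: Sequence[Classifier],
    mixing_fractions: Sequence[float] = (0.0, 0.5, 1.0),
    replicates: int = 3,
    seed: int = 0,
    total_size: int | None = None,
) -> list[UtilityResult]:
    """AUC on real test data for training mixes of real and synthetic rows.

    For each fraction f the training set has `total_size` rows (default: the
    size of `train_real`), with round(f * n) synthetic rows and the rest real,
    each subsampled without replacement with a per-replicate seed; the total
    size is held fixed so the comparison isolates the composition effect.
    f=0 is train-on-real, f=1 is train-on-synthetic.  Requesting more rows
    than a source holds is an error.
    """
    for f in mixing_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    results: list[UtilityResult] = []
    n_total = train_real.n if total_size is None else int(total_size)
    for rep in range(replicates):
        rep_seed = seed + rep
        for f in mixing_fractions:
            rng = np.random.default_rng([rep_seed, int(round(f * 10_000))])
            n_syn = int(round(f * n_total))
            n_real = n_total - n_syn
            parts_x, parts_y = [], []
            if n_real:
                x, y = _stratified_subsample(train_real, n_real, rng)
                parts_x.append(x); parts_y.append(y)
            if n_syn:
                x, y = _stratified_subsample(synthetic, n_syn, rng)
                parts_x.append(x); parts_y.append(y)
            train_x = np.concatenate(parts_x)
            train_y = np.concatenate(parts_y)
            for clf in classifiers:
                clf.fit(train_x, train_y)
                scores = clf.score(test.values)
                results.append(UtilityResult(
                    classifier=clf.name,
                    synthetic_fraction=float(f),
                    replicate=rep,
                    seed=rep_seed,
                    auc=auc_score(test.labels, scores),
                ))
    return results


def summarize_results(results: Sequence[UtilityResult]) -> pd.DataFrame:
    """Mean and variance of AUC per (classifier, fraction) across replicates."""
    df = pd.DataFrame([vars(r) for r in results])
    return (
        df.groupby(["classifier", "synthetic_fraction"])["auc"]
        .agg(mean_auc="mean", var_auc="var")
        .reset_index()
    )
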