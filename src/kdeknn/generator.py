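"""Privacy-aware synthetic data generation: KDE sampling with dual validation.

Pipeline, run on preprocessed (imputed + z-scored) training data:

1. Fit a KNN classifier on the full, imbalanced training set — the utility
   validator.
2. Partition the training set by class and fit one Gaussian KDE per class
   (bandwidth by Scott's rule unless overridden).
3. Compute the privacy reference sigma: the mean nearest-other-record distance
   within the real training set.  The acceptance threshold is
   ``sigma_multiplier * sigma``.
4. Iterate: draw a batch of candidates from each class's KDE; discard
   candidates the validator assigns to the wrong class (utility rejection);
   discard candidates closer than the threshold to any real training record
   (privacy rejection, strict: kept iff DCR >= threshold); keep survivors
   until each class reaches its target.

The result is a balanced synthetic dataset in standardized space, every record
of which (a) the validator classifies as its intended class and (b) sits at
least one threshold away from every real record — an empirical, not a
differential-privacy, guarantee.  A :class:`GenerationReport` accounts for
every candidate drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datasets import TabularDataset, write_csv_dataset
from .errors import ConvergenceError, DataError, FitError
from .kde import KDEModel, fit_kde, sample_kde
from .knn import fit_knn, predict, validate_candidates
from .preprocess import PreprocessModel
from .privacy import dcr_real_real, dcr_synthetic

__all__ = [
    "GeneratorConfig",
    "GenerationReport",
    "ClassCounts",
    "partition_by_class",
    "generate",
    "export_synthetic",
]


@dataclass
class GeneratorConfig:
    """All knobs of the generation loop.

    Defaults follow the method's reference configuration: validator k=5,
    privacy threshold equal to one sigma (the mean real nearest-record
    distance), balanced targets of 540 records per class, batch size equal to
    the per-class target.
    """

    k_neighbors: int = 5
    sigma_multiplier: float = 1.0
    target_positive: int = 540
    target_negative: int = 540
    batch_size: Optional[int] = None  # default: the per-class target
    max_iterations: int = 100
    bandwidth_positive: Optional[float] = None
    bandwidth_negative: Optional[float] = None
    kernel_mode: str = "isotropic"
    seed: int = 0
    utility_validation: bool = True
    privacy_validation: bool = True

    def validate(self) -> None:
        if self.target_positive < 0 or self.target_negative < 0:
            raise ValueError("targets must be >= 0")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.sigma_multiplier < 0:
            raise ValueError("sigma_multiplier must be >= 0")


@dataclass
class ClassCounts:
    """Candidate accounting for one class: drawn = accepted + rejections."""

    drawn: int = 0
    rejected_utility: int = 0
    rejected_privacy: int = 0
    accepted: int = 0


@dataclass
class GenerationReport:
    """Run summary: realized sigma, thresholds, bandwidths and accounting."""

    sigma_reference: float
    threshold: float
    bandwidth_positive: float
    bandwidth_negative: float
    seed: int
    iterations: int = 0
    positive: ClassCounts = field(default_factory=ClassCounts)
    negative: ClassCounts = field(default_factory=ClassCounts)

    def to_dict(self) -> dict:
        return {
            "sigma_reference": self.sigma_reference,
            "threshold": self.threshold,
            "bandwidth_positive": self.bandwidth_positive,
            "bandwidth_negative": self.bandwidth_negative,
            "seed": self.seed,
            "iterations": self.iterations,
            "positive": vars(self.positive).copy(),
            "negative": vars(self.negative).copy(),
        }


def partition_by_class(train: TabularDataset) -> tuple[TabularDataset, TabularDataset]:
    """Split into (positive-class subset, negative-class subset)."""
    pos = train.labels == 1
    neg = train.labels == 0
    if not pos.any() or not neg.any():
        raise DataError("both classes must be present")
    return train.subset(pos), train.subset(neg)


def _class_rng(seed: int, class_label: int) -> np.random.Generator:
    """One reproducible stream per class; documented so ablations are exact."""
    return np.random.default_rng([seed, class_label])


def generate(
    train: TabularDataset,
    config: GeneratorConfig,
) -> tuple[TabularDataset, GenerationReport]:
    """Run the full generation pipeline on a preprocessed training set.

    Returns a balanced synthetic dataset (positive rows first, then negative)
    with exactly the configured number of records per class, plus the run
    report.  Surplus survivors in the final batch are truncated in draw order.

    Raises
    ------
    ConvergenceError
        The iteration cap was reached before both targets were met; the
        partial report rides on the exception.
    """
    config.validate()
    if np.isnan(train.values).any():
        raise DataError("training data contains missing values; preprocess first")
    pos_set, neg_set = partition_by_class(train)
    if pos_set.n < 2 or neg_set.n < 2:
        raise FitError("each class needs at least 2 records to fit its KDE")

    validator = fit_knn(train, config.k_neighbors)
    kde_pos = fit_kde(pos_set.values, config.bandwidth_positive, config.kernel_mode)
    kde_neg = fit_kde(neg_set.values, config.bandwidth_negative, config.kernel_mode)

    sigma = dcr_real_real(train.values).mean
    threshold = config.sigma_multiplier * sigma
    report = GenerationReport(
        sigma_reference=sigma,
        threshold=threshold,
        bandwidth_positive=kde_pos.h,
        bandwidth_negative=kde_neg.h,
        seed=config.seed,
    )

    classes = {
        1: (kde_pos, config.target_positive, report.positive, _class_rng(config.seed, 1)),
        0: (kde_neg, config.target_negative, report.negative, _class_rng(config.seed, 0)),
    }
    kept: dict[int, list[np.ndarray]] = {1: [], 0: []}
    kept_n = {1: 0, 0: 0}

    for _ in range(config.max_iterations):
        if all(kept_n[c] >= classes[c][1] for c in (1, 0)):
            break
        report.iterations += 1
        for label in (1, 0):
            model, target, counts, rng = classes[label]
            if kept_n[label] >= target:
                continue
            batch = config.batch_size if config.batch_size is not None else target
            candidates = sample_kde(model, batch, rng)
            counts.drawn += batch
            if config.utility_validation:
                ok = validate_candidates(validator, candidates, label)
                counts.rejected_utility += int((~ok).sum())
                candidates = candidates[ok]
            if config.privacy_validation and candidates.shape[0]:
                dcr = dcr_synthetic(candidates, train.values).distances
                ok = dcr >= threshold
                counts.rejected_privacy += int((~ok).sum())
                candidates = candidates[ok]
            counts.accepted += candidates.shape[0]
            if candidates.shape[0]:
                kept[label].append(candidates)
                kept_n[label] += candidates.shape[0]
    else:
        if any(kept_n[c] < classes[c][1] for c in (1, 0)):
            raise ConvergenceError(
                f"targets not met after {config.max_iterations} iterations "
                f"(positive {kept_n[1]}/{config.target_positive}, "
                f"negative {kept_n[0]}/{config.target_negative}); "
                "consider lowering sigma_multiplier or the bandwidth",
                report=report,
            )

    def _stack(label: int, target: int) -> np.ndarray:
        if target == 0 or not kept[label]:
            return np.empty((0, train.d))
        return np.concatenate(kept[label])[:target]

    pos_rows = _stack(1, config.target_positive)
    neg_rows = _stack(0, config.target_negative)
    values = np.concatenate([pos_rows, neg_rows])
    labels = np.concatenate(
        [np.ones(pos_rows.shape[0], dtype=int), np.zeros(neg_rows.shape[0], dtype=int)]
    )
    synthetic = TabularDataset(values, labels, list(train.feature_names),
                               train.label_name)
    return synthetic, report


def export_synthetic(
    synthetic_std: TabularDataset,
    preprocess: PreprocessModel,
    path,
) -> None:
    """Inverse-standardize synthetic records and write them as CSV."""
    write_csv_dataset(preprocess.invert(synthetic_std), path)
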