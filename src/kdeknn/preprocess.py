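"""Median imputation and z-score standardization, fitted on training data only.

Missing cells are filled with the per-feature median of the *observed* training
values; every feature is then centred and scaled with the training mean and
sample standard deviation (ddof=1).  The transform is invertible so synthetic
records generated in standardized space can be exported in original clinical
units.  Statistics are never refitted on test or external data — that would
leak information across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import TabularDataset
from .errors import DataError, FitError, NotFittedError, SchemaError

__all__ = ["PreprocessModel", "fit_preprocessor"]


@dataclass
class PreprocessModel:
    """Per-feature imputation and standardization statistics (training units)."""

    feature_names: list[str]
    medians: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    fitted: bool = False

    def _check(self, data: TabularDataset) -> None:
        if not self.fitted:
            raise NotFittedError("preprocessor has not been fitted")
        if list(data.feature_names) != list(self.feature_names):
            raise SchemaError(
                "feature names do not match the fitted preprocessor"
            )

    def apply(self, data: TabularDataset) -> TabularDataset:
        """Impute with training medians, then z-score with training stats."""
        self._check(data)
        x = data.values.copy()
        mask = np.isnan(x)
        x[mask] = np.broadcast_to(self.medians, x.shape)[mask]
        x = (x - self.means) / self.stds
        return TabularDataset(x, data.labels, list(data.feature_names),
                              data.label_name)

    def invert(self, data: TabularDataset) -> TabularDataset:
        """Map standardized values back to original units: x*std + mean."""
        self._check(data)
        x = data.values * self.stds + self.means
        return TabularDataset(x, data.labels, list(data.feature_names),
                              data.label_name)


def fit_preprocessor(train: TabularDataset) -> PreprocessModel:
    """Fit imputation medians and standardization statistics on `train`.

    Medians are computed over observed values only; means and standard
    deviations over the imputed matrix.  Features with no observed value or
    zero post-imputation variance are rejected — they carry no usable signal
    and would make the z-score undefined.
    """
    x = train.values
    if x.shape[0] < 1:
        raise DataError("cannot fit a preprocessor on an empty dataset")
    observed = ~np.isnan(x)
    all_missing = ~observed.any(axis=0)
    if all_missing.any():
        bad = [train.feature_names[j] for j in np.flatnonzero(all_missing)]
        raise FitError(f"features with no observed values: {bad}")
    medians = np.nanmedian(x, axis=0)
    imputed = np.where(observed, x, medians)
    means = imputed.mean(axis=0)
    # sample std (ddof=1); a single row would give NaN, treat as constant
    stds = imputed.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    constant = ~(stds > 0)
    if constant.any():
        bad = [train.feature_names[j] for j in np.flatnonzero(constant)]
        raise FitError(f"constant features (zero variance): {bad}")
    return PreprocessModel(
        feature_names=list(train.feature_names),
        medians=medians,
        means=means,
        stds=stds,
        fitted=True,
    )
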