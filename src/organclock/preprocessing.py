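"""Preprocessing contract: center split, missingness filter, KNN
imputation with k = sqrt(n_train), train-anchored z-scoring.

All statistics (neighbor reference set, scaler means/SDs) are fitted on
the training split only and applied unchanged to test data, so held-out
evaluation stays honest.  The enforced order is filter -> impute -> scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer
from sklearn.utils.validation import check_is_fitted


@dataclass
class SampleSplit:
    train_centers: list[str]
    test_centers: list[str]
    train_ids: list[str]
    test_ids: list[str]

    def summary(self) -> dict:
        return {
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
            "train_centers": self.train_centers,
            "test_centers": self.test_centers,
        }


def split_by_center(samples: pd.DataFrame, train_center_ids: list[str]) -> SampleSplit:
    """Partition samples into train/test purely by collection center."""
    if "center" not in samples.columns:
        raise ValueError("samples must carry a 'center' column")
    id_col = "subject_id" if "subject_id" in samples.columns else "sample_id"
    centers = set(samples["center"].unique())
    train_centers = sorted(set(train_center_ids))
    unknown = set(train_centers) - centers
    if unknown:
        raise ValueError(f"train centers not present in samples: {sorted(unknown)}")
    if not train_centers or set(train_centers) == centers:
        raise ValueError("train centers must be a non-empty proper subset of all centers")
    is_train = samples["center"].isin(train_centers)
    return SampleSplit(
        train_centers=train_centers,
        test_centers=sorted(centers - set(train_centers)),
        train_ids=samples.loc[is_train, id_col].tolist(),
        test_ids=samples.loc[~is_train, id_col].tolist(),
    )


def filter_high_missingness(
    matrix: pd.DataFrame, threshold: float = 0.10
) -> tuple[list[str], pd.DataFrame]:
    """Retain proteins whose missing fraction is <= threshold.

    "Over threshold" is strict: a protein missing in exactly 10% of
    samples survives a 0.10 threshold.  Returns the retained protein list
    and a report of removed proteins with their missing fractions.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    frac = matrix.isna().mean(axis=0)
    removed = frac[frac > threshold]
    retained = [p for p in matrix.columns if p not in removed.index]
    report = removed.rename("missing_fraction").rename_axis("protein").reset_index()
    return retained, report


def choose_k(n_train: int) -> int:
    """Neighbor count for imputation: sqrt(n_train), rounded to the
    nearest integer (half away from zero), floor 1."""
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    return max(1, int(math.floor(math.sqrt(n_train) + 0.5)))


class CohortImputer(BaseEstimator, TransformerMixin):
    """KNN imputer with k = sqrt(n_train), fitted on training samples only.

    An imputed entry is the mean of the k nearest training samples'
    values for that protein, with nearness measured by Euclidean distance
    over co-observed proteins (nan-aware, proportionally rescaled).
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None) -> "CohortImputer":
        self._check_rows(X)
        self.k_ = self.k if self.k is not None else choose_k(len(X))
        self.proteins_ = list(X.columns)
        self._imputer_ = KNNImputer(n_neighbors=self.k_)
        self._imputer_.fit(X.to_numpy(float))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "k_")
        missing = set(X.columns) - set(self.proteins_)
        if missing:
            raise ValueError(f"proteins absent from the fitted imputer: {sorted(missing)}")
        self._check_rows(X)
        arr = self._imputer_.transform(X[self.proteins_].to_numpy(float))
        out = pd.DataFrame(arr, index=X.index, columns=self.proteins_)
        return out[list(X.columns)]

    @staticmethod
    def _check_rows(X: pd.DataFrame) -> None:
        all_missing = X.isna().all(axis=1)
        if all_missing.any():
            bad = list(X.index[all_missing])[:5]
            raise ValueError(f"samples with every protein missing: {bad}")


@dataclass
class ScalerParams:
    means: pd.Series
    sds: pd.Series

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}


class TrainAnchoredScaler(BaseEstimator, TransformerMixin):
    """Z-score by the training split's per-protein mean and SD."""

    def fit(self, X: pd.DataFrame, y=None) -> "TrainAnchoredScaler":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        zero = sds[sds <= 0]
        if len(zero):
            raise ValueError(
                f"zero-variance training proteins: {list(zero.index)[:5]}"
            )
        self.params_ = ScalerParams(means=means, sds=sds)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        p = self.params_
        return (X - p.means[X.columns]) / p.sds[X.columns]


# ---- thin functional wrappers over the estimator surface -----------------

def fit_impute(train_matrix: pd.DataFrame, k: int | None = None) -> CohortImputer:
    return CohortImputer(k=k).fit(train_matrix)


def apply_impute(model: CohortImputer, matrix: pd.DataFrame) -> pd.DataFrame:
    return model.transform(matrix)


def fit_scaler(train_matrix: pd.DataFrame) -> TrainAnchoredScaler:
    return TrainAnchoredScaler().fit(train_matrix)


def apply_scaler(scaler: TrainAnchoredScaler, matrix: pd.DataFrame) -> pd.DataFrame:
    return scaler.transform(matrix)


@dataclass
class PreprocessResult:
    split: SampleSplit
    retained: list[str]
    removed_report: pd.DataFrame
    imputer: CohortImputer
    scaler: TrainAnchoredScaler
    train: pd.DataFrame
    test: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def preprocess(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    train_center_ids: list[str],
    threshold: float = 0.10,
) -> PreprocessResult:
    """Run the full contract: split -> filter (global) -> impute -> scale.

    Missingness fractions are computed on the combined baseline matrix
    before splitting; imputer and scaler are fitted on training rows only.
    """
    split = split_by_center(samples, train_center_ids)
    retained, report = filter_high_missingness(matrix, threshold)
    mat = matrix[retained]
    train_raw = mat.loc[split.train_ids]
    test_raw = mat.loc[split.test_ids]
    imputer = fit_impute(train_raw)
    train_imp = imputer.transform(train_raw)
    test_imp = imputer.transform(test_raw)
    scaler = fit_scaler(train_imp)
    result = PreprocessResult(
        split=split,
        retained=retained,
        removed_report=report,
        imputer=imputer,
        scaler=scaler,
        train=scaler.transform(train_imp),
        test=scaler.transform(test_imp),
    )
    result.manifest = {
        "order": ["filter_high_missingness", "knn_impute", "z_scale"],
        "threshold": threshold,
        "k_neighbors": imputer.k_,
        "n_removed_proteins": len(report),
        **split.summary(),
    }
    return result
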