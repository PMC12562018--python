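"""Feature ranking and pruning: mutual information and RFE.

Two complementary selectors operate on the fixed feature schema:
``mutual_information_rank`` scores each column by the mutual information
(in bits, equal-frequency binning) between the binned feature and the
binary diagnosis label, and ``rfe_select`` recursively eliminates the
lowest-|weight| columns under an L2-regularized linear classifier fitted
on standardized inputs.  Both are exposed as sklearn-compatible
selector transformers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "mutual_information_rank",
    "rfe_select",
    "MutualInfoSelector",
    "RfeSelector",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Named feature columns plus a binary label vector."""

    values: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(self.values) != labels.shape[0]:
            raise ValueError("row count and label count differ")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values; "
                             "impute or drop before selection")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_column: str = "label",
                   positive: str = "PD") -> "FeatureMatrix":
        """Split a featurize_corpus-style frame into values + 0/1 labels,
        dropping columns that are entirely missing and median-imputing
        scattered holes."""
        labels = (frame[label_column].to_numpy() == positive).astype(int)
        values = frame.drop(columns=[label_column])
        values = values.dropna(axis=1, how="all")
        values = values.fillna(values.median(numeric_only=True))
        return cls(values, labels)


@dataclass(frozen=True)
class SelectionResult:
    """Ranked feature names with scores and the kept subset."""

    ranked_features: list[tuple[str, float]]
    kept: list[str]
    method: str


def _mi_bits(binned: np.ndarray, labels: np.ndarray) -> float:
    """Mutual information of two discrete variables, in bits."""
    joint = pd.crosstab(binned, labels).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_information_rank(data: FeatureMatrix, n_bins: int = 8,
                            n_keep: int | None = None) -> SelectionResult:
    """Rank columns by MI(binned feature; label) in bits.

    Binning is equal-frequency (quantile edges); ties in score are broken
    by schema order.  A perfectly label-identical feature on balanced
    classes scores 1 bit; an independent feature scores ~0.
    """
    if np.unique(data.labels).size < 2:
        raise ValueError("mutual information needs both classes present")
    scores = []
    for name in data.values.columns:
        col = data.values[name].to_numpy(dtype=float)
        edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
        binned = np.digitize(col, edges)
        scores.append((name, _mi_bits(binned, data.labels)))
    order = sorted(range(len(scores)), key=lambda i: -scores[i][1])
    ranked = [scores[i] for i in order]
    kept = [name for name, _ in ranked[:n_keep]] if n_keep else [n for n, _ in ranked]
    return SelectionResult(ranked, kept, "MI")


def rfe_select(data: FeatureMatrix, n_keep: int = 20,
               step: int = 1) -> SelectionResult:
    """Recursive feature elimination under a standardized L2 logistic
    scorer; drops ``step`` lowest-|weight| columns per round until
    ``n_keep`` remain.  Scores report the elimination ranking (1 = kept)."""
    n_cols = data.values.shape[1]
    if n_keep >= n_cols:
        raise ValueError("n_keep must be smaller than the column count")
    estimator = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=1.0, max_iter=2000)),  # L2 default
    ])
    # RFE needs coef_ on the wrapped object; expose via importance getter
    rfe = RFE(estimator, n_features_to_select=n_keep, step=step,
              importance_getter="named_steps.clf.coef_")
    rfe.fit(data.values.to_numpy(dtype=float), data.labels)
    names = list(data.values.columns)
    ranked = sorted(zip(names, rfe.ranking_.astype(float)), key=lambda t: t[1])
    kept = [name for name, rank in ranked if rank == 1.0]
    # preserve schema order within the kept set
    kept = [n for n in names if n in set(kept)]
    return SelectionResult(ranked, kept, "RFE")


class _BaseSelector(BaseEstimator):
    """Shared sklearn plumbing for the two selectors."""

    def transform(self, X) -> pd.DataFrame:
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        return frame[self.kept_]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)

    def get_support(self, indices: bool = False):
        names = list(self.feature_names_in_)
        mask = np.array([n in set(self.kept_) for n in names])
        return np.flatnonzero(mask) if indices else mask


class MutualInfoSelector(_BaseSelector):
    """Keep the ``n_keep`` columns with highest MI against the label."""

    def __init__(self, n_keep: int = 20, n_bins: int = 8):
        self.n_keep = n_keep
        self.n_bins = n_bins

    def fit(self, X, y) -> "MutualInfoSelector":
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        data = FeatureMatrix(frame, np.asarray(y))
        result = mutual_information_rank(data, self.n_bins, self.n_keep)
        self.feature_names_in_ = list(frame.columns)
        self.result_ = result
        self.kept_ = [n for n in frame.columns if n in set(result.kept)]
        return self


class RfeSelector(_BaseSelector):
    """Keep ``n_keep`` columns surviving recursive elimination."""

    def __init__(self, n_keep: int = 20, step: int = 1):
        self.n_keep = n_keep
        self.step = step

    def fit(self, X, y) -> "RfeSelector":
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        data = FeatureMatrix(frame, np.asarray(y))
        result = rfe_select(data, self.n_keep, self.step)
        self.feature_names_in_ = list(frame.columns)
        self.result_ = result
        self.kept_ = result.kept
        return self
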