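"""Metabolite abundance normalization and missing-value imputation.

Two steps, applied in this order:

1. **Median rescaling** — every metabolite's non-missing values are divided
   by their median, so each column's median becomes exactly 1.
2. **Half-minimum imputation** — each missing (below-detection-limit) cell
   is replaced by half the smallest observed value of that metabolite
   across all samples.

Both are exposed as scikit-learn transformers operating on DataFrames (so
they compose into pipelines) and as one-call functions on
:class:`~metsynkit.containers.MetaboliteTable`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import MetaboliteTable

__all__ = ["MedianRescaler", "HalfMinImputer", "median_rescale",
           "impute_half_min", "preprocess"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _check_no_empty_columns(df: pd.DataFrame, what: str) -> None:
    empty = df.columns[df.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"cannot {what}: all values missing for "
                         f"metabolite(s) {list(empty[:5])}")


class MedianRescaler(TransformerMixin, BaseEstimator):
    """Divide each column by its non-missing median (median becomes 1).

    Stateless in spirit — ``fit`` records the per-column medians of the data
    it sees so the same scaling can be applied to new samples, but typical
    use is ``fit_transform`` on the full cohort matrix.
    """

    def fit(self, X, y=None):
        df = _as_frame(X)
        _check_no_empty_columns(df, "rescale")
        medians = df.median(axis=0, skipna=True)
        if (medians <= 0).any():
            bad = list(medians.index[medians <= 0][:5])
            raise ValueError(f"non-positive median for metabolite(s) {bad}")
        self.medians_ = medians
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "medians_")
        df = _as_frame(X)
        if df.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return df / self.medians_


class HalfMinImputer(TransformerMixin, BaseEstimator):
    """Replace missing cells by 0.5 × the column's minimum observed value."""

    def fit(self, X, y=None):
        df = _as_frame(X)
        _check_no_empty_columns(df, "impute")
        self.fill_values_ = 0.5 * df.min(axis=0, skipna=True)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "fill_values_")
        df = _as_frame(X)
        if df.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return df.fillna(self.fill_values_)


def median_rescale(table: MetaboliteTable) -> MetaboliteTable:
    """Median-rescale a metabolite table (missing cells stay missing)."""
    scaled = MedianRescaler().fit_transform(table.abundances)
    return MetaboliteTable(scaled, table.annotations)


def impute_half_min(table: MetaboliteTable) -> MetaboliteTable:
    """Half-minimum-impute a metabolite table (no missing cells remain)."""
    filled = HalfMinImputer().fit_transform(table.abundances)
    return MetaboliteTable(filled, table.annotations)


def preprocess(table: MetaboliteTable, impute: bool = True) -> MetaboliteTable:
    """Standard pipeline: median rescaling first, then half-min imputation.

    The order is fixed (and pinned by a regression test): rescaling uses
    only observed values, imputation then fills on the normalized scale.
    """
    out = median_rescale(table)
    if impute:
        out = impute_half_min(out)
    return out
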