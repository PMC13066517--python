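"""Percent-of-total and mean-scaled relative-binding normalization.

Read counts are compositional: only within-sample proportions are
meaningful.  Counts are first converted to the percentage of each sample's
total reads, then each sequence's percentages are divided by that
sequence's mean percentage across the samples in scope.  The resulting
scaled value is 1 when a sequence shows no deviation from its mean
relative binding, below 1 for reduced and above 1 for increased binding.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["to_percent", "to_scaled", "RelativeBindingScaler"]


def to_percent(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-total per sample (CountMatrix orientation: rows=sequences)."""
    totals = counts.sum(axis=0)
    zero = [c for c in counts.columns if totals[c] == 0]
    if zero:
        raise ValueError(f"samples with zero total reads: {zero}")
    return 100.0 * counts / totals


def to_scaled(percent: pd.DataFrame, scope: pd.DataFrame | None = None) -> pd.DataFrame:
    """Divide each sequence's percent values by its mean percent.

    ``scope`` optionally supplies the matrix over which the per-sequence
    means are taken (default: ``percent`` itself, i.e. the cohort being
    analyzed).
    """
    ref = percent if scope is None else scope
    means = ref.mean(axis=1)
    zero = [s for s in percent.index if means.get(s, 0) == 0]
    if zero:
        raise ValueError(f"sequences with zero mean percent: {zero[:5]}")
    return percent.div(means, axis=0)


class RelativeBindingScaler(TransformerMixin, BaseEstimator):
    """Transformer form: X is samples x sequences.

    ``fit`` records per-sequence mean percentages over the fitted cohort;
    ``transform`` returns scaled relative-binding values.  Fit and
    transform on the same cohort reproduces the pipeline's default
    per-cohort scaling scope.
    """

    def fit(self, X: pd.DataFrame, y=None):
        percent = to_percent(X.T)
        self.mean_percent_ = percent.mean(axis=1)
        zero = [s for s in self.mean_percent_.index if self.mean_percent_[s] == 0]
        if zero:
            raise ValueError(f"sequences with zero mean percent: {zero[:5]}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_percent_")
        percent = to_percent(X.T)
        missing = [s for s in percent.index if s not in self.mean_percent_.index]
        if missing:
            raise ValueError(f"sequences unseen at fit time: {missing[:5]}")
        return percent.div(self.mean_percent_.reindex(percent.index), axis=0).T
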