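"""Per-sequence OLS contrasts with BH-FDR and effect-size thresholds.

For each retained sequence the scaled relative-binding values are regressed
on an intercept plus a study-group indicator, using only the samples in the
reference and study groups of the contrast.  With a binary predictor the
coefficient equals the between-group difference in mean scaled binding, and
its two-sided t test (df = n - 2) is algebraically the pooled-variance
two-sample t test.  P values are Benjamini-Hochberg adjusted within the
contrast; a sequence is called *descriptive* when the adjusted p is at most
``fdr_q`` and the absolute coefficient reaches the effect threshold
``coef_threshold`` (1.0 for sampling-time contrasts, where large
compositional shifts are expected between colostrum and mature milk; 0.2
for the subtler BMI-group and parity conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastSpec",
    "DescriptiveOLS",
    "ols_contrast",
    "benjamini_hochberg",
    "summarize_contrasts",
    "unique_descriptive",
    "DEFAULT_CONTRASTS",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison on a metadata column."""

    condition: str
    reference: str
    study: str
    coef_threshold: float = 0.2
    fdr_q: float = 0.05

    def __post_init__(self):
        if self.coef_threshold <= 0:
            raise ValueError("coef_threshold must be > 0")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @property
    def name(self) -> str:
        return f"{self.condition}:{self.reference}_vs_{self.study}"


def default_contrasts(
    timepoints=("3d", "1m", "2m", "3m"),
    time_threshold: float = 1.0,
    group_threshold: float = 0.2,
    fdr_q: float = 0.05,
) -> list:
    """The study's contrast structure: each later timepoint vs the 3-day
    reference at threshold 1.0; elevated-vs-normal BMI and primiparous-vs-
    multiparous at threshold 0.2."""
    specs = [
        ContrastSpec("timepoint", timepoints[0], tp, time_threshold, fdr_q)
        for tp in timepoints[1:]
    ]
    specs.append(ContrastSpec("bmi_group", "normal", "elevated", group_threshold, fdr_q))
    specs.append(ContrastSpec("parity", "multiparous", "primiparous", group_threshold, fdr_q))
    return specs


DEFAULT_CONTRASTS = default_contrasts()


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DescriptiveOLS(BaseEstimator):
    """Fit one two-group OLS contrast per sequence.

    Parameters follow :class:`ContrastSpec`; ``fit(X, y)`` takes a
    samples x sequences scaled matrix and a per-sample label vector and
    uses only samples labelled with the reference or study level.

    Attributes
    ----------
    results_ : DataFrame indexed by sequence with columns
        ``beta, p_raw, p_adj, direction, descriptive``.
    """

    def __init__(self, reference: str = "normal", study: str = "elevated",
                 coef_threshold: float = 0.2, fdr_q: float = 0.05):
        self.reference = reference
        self.study = study
        self.coef_threshold = coef_threshold
        self.fdr_q = fdr_q

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        ref_mask = (y == self.reference).to_numpy()
        study_mask = (y == self.study).to_numpy()
        n1, n2 = int(ref_mask.sum()), int(study_mask.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"need >= 2 samples per group; got {n1} reference, {n2} study"
            )
        A = X.to_numpy(dtype=float)[ref_mask]
        B = X.to_numpy(dtype=float)[study_mask]
        mean_ref, mean_study = A.mean(axis=0), B.mean(axis=0)
        beta = mean_study - mean_ref
        ss_within = ((A - mean_ref) ** 2).sum(axis=0) + ((B - mean_study) ** 2).sum(axis=0)
        df = n1 + n2 - 2
        sigma2 = ss_within / df
        se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        degenerate = se == 0
        if degenerate.any():
            # zero residual variance: constant sequences get p = 1; perfectly
            # separated group constants are unambiguous (p = 0)
            warnings.warn(
                f"{int(degenerate.sum())} sequence(s) with zero residual variance",
                stacklevel=2,
            )
            p[degenerate & (beta == 0)] = 1.0
            p[degenerate & (beta != 0)] = 0.0
        p_adj = benjamini_hochberg(p)
        descriptive = (p_adj <= self.fdr_q) & (np.abs(beta) >= self.coef_threshold)
        self.results_ = pd.DataFrame(
            {
                "beta": beta,
                "p_raw": p,
                "p_adj": p_adj,
                "direction": np.where(beta >= 0, "increased", "decreased"),
                "descriptive": descriptive,
            },
            index=pd.Index(X.columns, name="sequence"),
        )
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        check_is_fitted(self, "results_")
        return self.results_["descriptive"].to_numpy()

    @property
    def panel_(self):
        check_is_fitted(self, "results_")
        return sorted(self.results_.index[self.results_["descriptive"]])


def ols_contrast(scaled: pd.DataFrame, meta: pd.DataFrame, spec: ContrastSpec) -> pd.DataFrame:
    """CountMatrix-oriented wrapper (scaled: sequences x samples).

    Returns the per-sequence results table for one contrast.
    """
    labels = meta.set_index("sample_id")[spec.condition].reindex(scaled.columns)
    if labels.isna().any():
        missing = list(scaled.columns[labels.isna()])
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    present = set(labels)
    for lvl in (spec.reference, spec.study):
        if lvl not in present:
            raise ValueError(f"level {lvl!r} absent from metadata column {spec.condition!r}")
    est = DescriptiveOLS(
        reference=spec.reference,
        study=spec.study,
        coef_threshold=spec.coef_threshold,
        fdr_q=spec.fdr_q,
    ).fit(scaled.T, labels)
    out = est.results_.copy()
    out.insert(0, "contrast", spec.name)
    return out


def summarize_contrasts(results: dict) -> pd.DataFrame:
    """Per-contrast counts of increased/decreased descriptive sequences.

    ``results`` maps contrast name -> per-sequence results table.
    """
    rows = []
    for name, res in results.items():
        desc = res[res["descriptive"]]
        rows.append(
            {
                "contrast": name,
                "n_descriptive": len(desc),
                "n_increased": int((desc["direction"] == "increased").sum()),
                "n_decreased": int((desc["direction"] == "decreased").sum()),
            }
        )
    return pd.DataFrame(rows)


def unique_descriptive(results: dict, condition: str | None = None) -> list:
    """Union of descriptive sequences, optionally restricted to contrasts of
    one condition (e.g. the pooled sampling-time panel over the three
    later-vs-3-days comparisons)."""
    seqs = set()
    for name, res in results.items():
        if condition is not None and not name.startswith(condition + ":"):
            continue
        seqs.update(res.index[res["descriptive"]])
    return sorted(seqs)
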