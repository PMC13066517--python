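"""Independent-cohort validation of a descriptive-sequence panel.

A panel discovered on one cohort is frozen and applied to a second cohort:
the scaled relative-binding values of the panel sequences are summarized by
an (unscaled, mean-centered) PCA, and the first principal component score
per sample is compared between condition groups with Wilcoxon rank-sum
tests.  Group medians and unbiased variances describe location and
dispersion of each group along PC1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PanelValidation",
    "PanelPCA",
    "pca_panel",
    "wilcoxon_rank_sum",
    "validate_panel",
]


@dataclass
class PanelValidation:
    panel: list
    panel_coverage: float
    pc1_scores: pd.Series
    explained_variance_ratio: np.ndarray
    group_medians: dict = field(default_factory=dict)
    group_variances: dict = field(default_factory=dict)
    wilcoxon_p: dict = field(default_factory=dict)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact null distribution when both groups have at most 25 observations
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


class PanelPCA(BaseEstimator):
    """PCA restricted to a sequence panel with a deterministic sign.

    ``fit(X, y)`` takes a samples x sequences scaled matrix plus per-sample
    group labels.  Each panel sequence is mean-centered across samples (no
    unit-variance scaling: scaled binding values already share the mean-1
    scale); scores come from the SVD of the centered matrix.  PC1 is
    oriented so that the study group's median score is >= the reference
    group's, making repeated runs bit-identical.
    """

    def __init__(self, panel=(), reference=None, study=None):
        self.panel = panel
        self.reference = reference
        self.study = study

    def fit(self, X: pd.DataFrame, y=None):
        panel = sorted(set(self.panel))
        if not panel:
            raise ValueError("empty panel")
        present = [s for s in panel if s in X.columns]
        if not present:
            raise ValueError("no panel sequence present in the matrix")
        if len(present) < len(panel):
            warnings.warn(
                f"{len(panel) - len(present)} of {len(panel)} panel sequences "
                "absent from the validation matrix",
                stacklevel=2,
            )
        if len(present) < 2 or X.shape[0] < 3:
            raise ValueError("need >= 2 panel sequences and >= 3 samples")
        self.coverage_ = len(present) / len(panel)
        self.panel_present_ = present

        M = X[present].to_numpy(dtype=float)
        M = M - M.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        scores = U * S
        var = S**2
        self.explained_variance_ratio_ = var / var.sum() if var.sum() > 0 else var
        pc1 = pd.Series(scores[:, 0], index=X.index, name="PC1")
        if self.reference is not None and self.study is not None and y is not None:
            y = pd.Series(np.asarray(y, dtype=object), index=X.index)
            med_study = pc1[(y == self.study).to_numpy()].median()
            med_ref = pc1[(y == self.reference).to_numpy()].median()
            if med_study < med_ref:
                pc1 = -pc1
        else:
            # fall back to a data-only convention: largest-|loading| positive
            lead = int(np.argmax(np.abs(Vt[0])))
            if Vt[0][lead] < 0:
                pc1 = -pc1
        self.pc1_scores_ = pc1
        self.n_features_in_ = X.shape[1]
        return self


def pca_panel(scaled: pd.DataFrame, panel, *, meta=None, reference=None, study=None):
    """Sequences x samples wrapper returning a scores-level PanelValidation."""
    y = None
    if meta is not None and reference is not None:
        y = meta.set_index("sample_id").loc[list(scaled.columns)].iloc[:, 0]
    est = PanelPCA(panel=panel, reference=reference, study=study).fit(scaled.T, y)
    return PanelValidation(
        panel=sorted(set(panel)),
        panel_coverage=est.coverage_,
        pc1_scores=est.pc1_scores_,
        explained_variance_ratio=est.explained_variance_ratio_,
    )


def _group_pairs(grouping: str, levels) -> list:
    if grouping == "timepoint":
        tps = list(levels)
        ref = tps[0]
        pairs = [(ref, tp) for tp in tps[1:]]
        if "1m" in tps and "3m" in tps:
            pairs.append(("1m", "3m"))
        return pairs
    if grouping == "bmi_group":
        return [("normal", "elevated")]
    if grouping == "parity":
        return [("multiparous", "primiparous")]
    raise ValueError(f"unknown grouping {grouping!r}")


def validate_panel(
    scaled: pd.DataFrame,
    meta: pd.DataFrame,
    panel,
    grouping: str,
    timepoints=("3d", "1m", "2m", "3m"),
) -> PanelValidation:
    """Full panel validation on one cohort.

    ``scaled`` is sequences x samples; ``grouping`` selects the condition
    (timepoint comparisons are each later timepoint vs the first, plus
    1 month vs 3 months; binary conditions give their single pair).
    """
    labels = meta.set_index("sample_id")[grouping].reindex(scaled.columns)
    if labels.isna().any():
        raise ValueError("samples missing from metadata")
    levels = timepoints if grouping == "timepoint" else sorted(set(labels))
    pairs = _group_pairs(grouping, levels)
    for lvl in {l for pair in pairs for l in pair}:
        if lvl not in set(labels):
            raise ValueError(f"group {lvl!r} absent from validation metadata")

    ref, study = pairs[0]
    est = PanelPCA(panel=panel, reference=ref, study=study).fit(scaled.T, labels)
    pc1 = est.pc1_scores_
    result = PanelValidation(
        panel=sorted(set(panel)),
        panel_coverage=est.coverage_,
        pc1_scores=pc1,
        explained_variance_ratio=est.explained_variance_ratio_,
    )
    for lvl in pd.unique(labels):
        vals = pc1[(labels == lvl).to_numpy()]
        result.group_medians[lvl] = float(vals.median())
        result.group_variances[lvl] = float(vals.var(ddof=1)) if len(vals) > 1 else 0.0
    for a, b in pairs:
        va = pc1[(labels == a).to_numpy()].to_numpy()
        vb = pc1[(labels == b).to_numpy()].to_numpy()
        result.wilcoxon_p[f"{a}_vs_{b}"] = wilcoxon_rank_sum(va, vb)
    return result
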