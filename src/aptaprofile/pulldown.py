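"""Pull-down proteomics relative-abundance profiles.

Protein intensities from candidate-aptamer pull-downs (plus negative
controls) are converted to per-sample log2 relative abundances,

    L[p, s] = log2(100 * I[p, s] / sum_p I[p, s]),

computed over all detected proteins of a sample so that the (linear-scale)
relative abundances sum to 100.  Cells with zero intensity are *not
detected* and carry no L value.  Proteins are classified as background
(detected in any negative control), model-unique (detected only in
pull-downs of a single model group) or shared.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "top_proteins",
    "flag_unique_proteins",
    "read_intensities",
]


def read_intensities(path) -> tuple:
    """Read a protein x sample intensity TSV whose first line maps samples
    to model groups (``#groups<TAB>g1<TAB>g2...``)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#groups":
            raise ValueError("first line must be a '#groups' header")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    groups = dict(zip(df.columns, header[1:]))
    return df, groups


def relative_abundance(
    intensities: pd.DataFrame, *, min_intensity: float = 0.0
) -> pd.DataFrame:
    """Log2 relative-abundance matrix; NaN marks not-detected cells."""
    I = intensities.astype(float).where(intensities > min_intensity, 0.0)
    if (I.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    totals = I.sum(axis=0)
    zero = [c for c in I.columns if totals[c] == 0]
    if zero:
        raise ValueError(f"samples with zero total intensity: {zero}")
    rel = 100.0 * I / totals
    with np.errstate(divide="ignore"):
        L = np.log2(rel.where(rel > 0))
    return L


def top_proteins(L: pd.DataFrame, n: int = 25) -> pd.DataFrame:
    """The n most enriched proteins by maximum L across samples, ordered by
    descending maximum (heatmap display order)."""
    ranked = L.max(axis=1).sort_values(ascending=False, kind="stable")
    return L.loc[ranked.index[:n]]


def flag_unique_proteins(
    L: pd.DataFrame, groups: dict, negative_labels=("negative",)
) -> pd.Series:
    """Classify proteins as background / model-unique(group) / shared.

    ``groups`` maps sample -> model-group label; samples whose label is in
    ``negative_labels`` are negative controls.  Detection is L being
    defined (intensity > 0), which makes the classification invariant to
    per-sample intensity rescaling.
    """
    detected = L.notna()
    neg_cols = [s for s in L.columns if groups.get(s) in set(negative_labels)]
    pos_cols = [s for s in L.columns if s not in neg_cols]
    if not neg_cols:
        warnings.warn(
            "no negative-control columns; classification limited to shared/unique",
            stacklevel=2,
        )
    labels = {}
    for prot in L.index:
        if neg_cols and detected.loc[prot, neg_cols].any():
            labels[prot] = "background"
            continue
        hit_groups = sorted(
            {groups[s] for s in pos_cols if detected.loc[prot, s]}
        )
        if not hit_groups:
            labels[prot] = "not_detected"
        elif len(hit_groups) == 1:
            labels[prot] = f"model-unique({hit_groups[0]})"
        else:
            labels[prot] = "shared"
    return pd.Series(labels, name="classification").reindex(L.index)
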