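"""Collapse near-identical reads into ancestor families and filter rare ones.

PCR and sequencing errors surround each truly selected aptamer with a cloud
of low-abundance derivatives.  ``FamilyJoiner`` assigns every observed
sequence to a high-abundance representative within a Damerau-Levenshtein
distance threshold (default 3), moving -- never dropping -- read counts.
``MinCountFilter`` then keeps only sequences detected with at least
``c_min`` reads (default 3) in the configured set of samples, which
suppresses missing-value bias downstream.

Both are scikit-learn style transformers over samples x sequences
DataFrames; :func:`join_families` / :func:`filter_min_count` are thin
wrappers taking the sequences x samples CountMatrix orientation used on
disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .distance import dl_distance, encode_many, nearest_within

__all__ = [
    "FilterConfig",
    "SequenceFamily",
    "FamilyJoiner",
    "MinCountFilter",
    "join_families",
    "filter_min_count",
]


@dataclass
class FilterConfig:
    """Thresholds of the joining + filtering stage."""

    d_max: int = 3
    c_min: int = 3
    presence_mode: str = "all_samples"  # or "any_sample", "mean"

    def __post_init__(self):
        if self.d_max < 0 or self.c_min < 0:
            raise ValueError("d_max and c_min must be >= 0")
        if self.presence_mode not in ("all_samples", "any_sample", "mean"):
            raise ValueError(f"unknown presence_mode {self.presence_mode!r}")


@dataclass
class SequenceFamily:
    representative: str
    members: dict = field(default_factory=dict)  # member sequence -> distance

    @property
    def size(self) -> int:
        return len(self.members)


class FamilyJoiner(TransformerMixin, BaseEstimator):
    """Greedy abundance-anchored joining of similar sequences.

    Sequences are visited in descending total-count order (ties broken
    lexicographically).  A sequence founds a new family iff no existing
    representative lies within ``d_max``; otherwise its counts are added to
    the nearest representative (ties resolve to the representative founded
    first, i.e. higher abundance, then lexicographic -- which is the
    founding order).  The greedy pass is deterministic and invariant to the
    input row order.

    Parameters
    ----------
    d_max : int, default 3
        Damerau-Levenshtein joining threshold.
    restricted : bool, default False
        Use the restricted (optimal string alignment) variant instead of
        the unrestricted metric.
    linkage : {"greedy", "single"}, default "greedy"
        "single" builds families as connected components of the <= d_max
        graph instead (exact but quadratic; for small inputs).

    Attributes
    ----------
    families_ : list of SequenceFamily
    assignment_ : dict mapping each input sequence to its representative
    """

    def __init__(self, d_max: int = 3, restricted: bool = False, linkage: str = "greedy"):
        self.d_max = d_max
        self.restricted = restricted
        self.linkage = linkage

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] == 0:
            raise ValueError("no sequences to join")
        if self.linkage not in ("greedy", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        totals = X.sum(axis=0)
        ordered = sorted(X.columns, key=lambda s: (-totals[s], s))
        if self.linkage == "greedy" and not self.restricted:
            assignment = self._greedy_fast(ordered)
        elif self.linkage == "greedy":
            assignment = self._greedy_python(ordered)
        else:
            assignment = self._single_linkage(ordered, totals)
        families: dict[str, SequenceFamily] = {}
        for seq in ordered:
            rep = assignment[seq]
            fam = families.setdefault(rep, SequenceFamily(rep))
            fam.members[seq] = dl_distance(rep, seq, restricted=self.restricted)
        self.families_ = list(families.values())
        self.assignment_ = assignment
        self.n_features_in_ = X.shape[1]
        return self

    def _greedy_fast(self, ordered):
        mat, lens = encode_many(ordered)
        max_len = mat.shape[1] + self.d_max + 1
        reps = np.zeros((len(ordered), max_len), dtype=np.uint8)
        rep_lens = np.zeros(len(ordered), dtype=np.int64)
        rep_seq: list[str] = []
        assignment: dict[str, str] = {}
        for i, seq in enumerate(ordered):
            q = np.zeros(max_len, dtype=np.uint8)
            q[: lens[i]] = mat[i, : lens[i]]
            idx, _ = nearest_within(q, lens[i], reps, rep_lens, len(rep_seq), self.d_max)
            if idx == -1:
                reps[len(rep_seq), : lens[i]] = mat[i, : lens[i]]
                rep_lens[len(rep_seq)] = lens[i]
                rep_seq.append(seq)
                assignment[seq] = seq
            else:
                assignment[seq] = rep_seq[idx]
        return assignment

    def _greedy_python(self, ordered):
        reps: list[str] = []
        assignment: dict[str, str] = {}
        for seq in ordered:
            best, best_d = None, self.d_max + 1
            for rep in reps:
                if abs(len(rep) - len(seq)) >= best_d:
                    continue
                d = dl_distance(rep, seq, restricted=self.restricted)
                if d < best_d:
                    best, best_d = rep, d
            if best is None:
                reps.append(seq)
                assignment[seq] = seq
            else:
                assignment[seq] = best
        return assignment

    def _single_linkage(self, ordered, totals):
        import networkx as g

        graph = g.Graph()
        graph.add_nodes_from(ordered)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                if abs(len(a) - len(b)) > self.d_max:
                    continue
                if dl_distance(a, b, restricted=self.restricted) <= self.d_max:
                    graph.add_edge(a, b)
        assignment = {}
        for comp in g.connected_components(graph):
            rep = min(comp, key=lambda s: (-totals[s], s))
            for s in comp:
                assignment[s] = rep
        return assignment

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Aggregate per-sample counts onto family representatives."""
        check_is_fitted(self, "assignment_")
        reps = [self.assignment_.get(s, s) for s in X.columns]
        joined = X.T.groupby(pd.Index(reps, name="sequence")).sum().T
        totals = joined.sum(axis=0)
        order = sorted(joined.columns, key=lambda s: (-totals[s], s))
        return joined[order]


class MinCountFilter(TransformerMixin, BaseEstimator):
    """Keep sequences with >= ``c_min`` reads per sample.

    ``presence_mode`` controls how "per sample" is read: require the
    threshold in every sample (default, minimizing missing values), in at
    least one sample, or on the across-sample mean.
    """

    def __init__(self, c_min: int = 3, presence_mode: str = "all_samples"):
        self.c_min = c_min
        self.presence_mode = presence_mode

    def fit(self, X: pd.DataFrame, y=None):
        FilterConfig(c_min=self.c_min, presence_mode=self.presence_mode)
        if self.presence_mode == "all_samples":
            keep = (X >= self.c_min).all(axis=0)
        elif self.presence_mode == "any_sample":
            keep = (X >= self.c_min).any(axis=0)
        else:
            keep = X.mean(axis=0) >= self.c_min
        self.support_ = keep
        self.retained_ = [s for s in X.columns if keep[s]]
        self.removed_ = [s for s in X.columns if not keep[s]]
        self.n_features_in_ = X.shape[1]
        if not self.retained_:
            raise ValueError(
                "min-count filter removed every sequence; review c_min "
                f"(={self.c_min}) or presence_mode (={self.presence_mode!r})"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return X[self.retained_]


def join_families(counts: pd.DataFrame, cfg: FilterConfig | None = None, **kw):
    """CountMatrix-oriented wrapper; returns ``(joined, families)``."""
    cfg = cfg or FilterConfig()
    joiner = FamilyJoiner(d_max=cfg.d_max, **kw).fit(counts.T)
    return joiner.transform(counts.T).T, joiner.families_


def filter_min_count(joined: pd.DataFrame, cfg: FilterConfig | None = None):
    """CountMatrix-oriented wrapper around :class:`MinCountFilter`."""
    cfg = cfg or FilterConfig()
    f = MinCountFilter(c_min=cfg.c_min, presence_mode=cfg.presence_mode)
    return f.fit_transform(joined.T).T
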