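"""K-mer motif enrichment and motif-defined candidate-aptamer families.

Descriptive sequences that share a conserved subsequence plausibly bind the
same or a similar protein epitope.  Homology among panel sequences is
operationalized as k-mer containment enrichment (default k = 7): for every
k-mer occurring in a panel, the number of panel sequences containing it is
compared with its empirical containment frequency in the full retained
library via a one-sided binomial tail test, BH-adjusted across k-mers.
The empirical background is used rather than an i.i.d. base model because
selection libraries are sequence-biased.  Enriched motifs are merged into
families when they share members or overlap by k-1 characters, and each
family nominates its highest-read-count member as the candidate for
pull-down synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg

__all__ = [
    "MotifFamily",
    "CandidateSelection",
    "motif_enrichment",
    "build_families",
    "select_candidates",
]


@dataclass
class MotifFamily:
    motifs: tuple  # merged enriched k-mers
    members: tuple  # sequences containing >= 1 family motif
    representative: str
    models: tuple = ()  # conditions whose panels contributed members

    @property
    def motif(self) -> str:
        return self.motifs[0]


@dataclass
class CandidateSelection:
    sequence: str
    family: MotifFamily
    high_read_count: bool = True
    conserved_motif: bool = True
    model_representation: bool = True

    @property
    def selected(self) -> bool:
        return self.high_read_count and self.conserved_motif and self.model_representation


def _kmers(seq: str, k: int):
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def _bh_full_family(p: np.ndarray, m_total: int) -> np.ndarray:
    """BH step-up over a family of ``m_total`` tests of which only the
    materialized ones (the rest have p = 1) are supplied."""
    p = np.asarray(p, dtype=float)
    m_total = max(m_total, p.size)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    stepped = np.minimum.accumulate((m_total * p[order] / ranks)[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(stepped, 1.0)
    return out


def motif_enrichment(
    panel,
    background,
    k: int = 7,
    *,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    alphabet: str = "ACGU",
) -> pd.DataFrame:
    """Enriched k-mers in a panel relative to the retained library.

    The BH family is *all* |alphabet|^k k-mers: k-mers absent from the
    panel trivially have p = 1, so only observed ones are materialized but
    the adjustment uses the full test count.  Conditioning the family on
    occurrence in the panel would make singleton k-mers (which occur by
    construction) reject themselves in bulk under the null.

    Returns a DataFrame indexed by k-mer with columns ``n_panel``,
    ``panel_frac``, ``background_frac``, ``fold``, ``p_raw``, ``p_adj``,
    ``enriched``, sorted by ascending p then k-mer.
    """
    panel = [str(s) for s in panel]
    background = [str(s) for s in background]
    if not panel:
        raise ValueError("empty panel")
    if any(len(s) < k for s in panel):
        raise ValueError(f"k={k} exceeds a panel sequence length")

    panel_hits: dict[str, int] = {}
    for s in panel:
        for km in _kmers(s, k):
            panel_hits[km] = panel_hits.get(km, 0) + 1
    bg_hits = {km: 0 for km in panel_hits}
    n_bg = len(background)
    for s in background:
        seen = _kmers(s, k) & bg_hits.keys()
        for km in seen:
            bg_hits[km] += 1

    n = len(panel)
    kmers = sorted(panel_hits)
    x = np.array([panel_hits[km] for km in kmers])
    # Background containment probability; a motif never seen in the library
    # gets a half-count pseudo-frequency so fold changes stay finite.
    p0 = np.array([max(bg_hits[km], 0.5) / max(n_bg, 1) for km in kmers])
    p0 = np.minimum(p0, 1.0)
    p_raw = stats.binom.sf(x - 1, n, p0)
    p_adj = _bh_full_family(p_raw, m_total=len(alphabet) ** k)
    frac = x / n
    fold = frac / p0
    out = pd.DataFrame(
        {
            "n_panel": x,
            "panel_frac": frac,
            "background_frac": p0,
            "fold": fold,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "enriched": (p_adj <= alpha) & (fold >= min_fold),
        },
        index=pd.Index(kmers, name="kmer"),
    )
    return out.sort_values(["p_raw", "kmer"], kind="stable")


def _share_overlap(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    return bool(_kmers(a, k) & _kmers(b, k))


def build_families(
    enrichment: pd.DataFrame,
    panels: dict,
    total_reads: pd.Series,
    *,
    member_overlap: float = 0.5,
) -> list:
    """Merge enriched motifs into families and annotate their models.

    ``panels`` maps a model name (condition) to its descriptive-sequence
    list; ``total_reads`` gives per-sequence summed reads over both cohorts
    (used to pick the family representative).  Motifs are merged
    transitively when their member sets overlap by >= ``member_overlap`` of
    the smaller set or the motif strings share a (k-1)-mer.
    """
    motifs = sorted(enrichment.index[enrichment["enriched"]])
    all_panel = sorted({s for seqs in panels.values() for s in seqs})
    members = {
        m: frozenset(s for s in all_panel if m in s) for m in motifs
    }
    k = len(motifs[0]) if motifs else 0

    graph = nx.Graph()
    graph.add_nodes_from(motifs)
    for i, a in enumerate(motifs):
        for b in motifs[i + 1:]:
            ma, mb = members[a], members[b]
            shared = len(ma & mb)
            smaller = min(len(ma), len(mb))
            if (smaller and shared / smaller >= member_overlap) or _share_overlap(a, b, k - 1):
                graph.add_edge(a, b)

    families = []
    for comp in nx.connected_components(graph):
        fam_motifs = tuple(sorted(comp))
        fam_members = tuple(sorted(set().union(*(members[m] for m in comp))))
        if not fam_members:
            continue
        rep = min(
            fam_members,
            key=lambda s: (-float(total_reads.get(s, 0.0)), s),
        )
        models = tuple(
            sorted(
                model
                for model, seqs in panels.items()
                if set(seqs) & set(fam_members)
            )
        )
        families.append(MotifFamily(fam_motifs, fam_members, rep, models))
    families.sort(key=lambda f: f.motifs)
    return families


def singleton_sequences(families, panels) -> list:
    """Panel sequences containing no enriched motif (reported separately)."""
    covered = {s for f in families for s in f.members}
    return sorted(
        {s for seqs in panels.values() for s in seqs} - covered
    )


def select_candidates(families, top_n, total_reads: pd.Series | None = None) -> list:
    """Pick the top families per model group by representative read count.

    ``top_n`` is either an int applied to every model group or a mapping
    from model-group annotation (tuple of conditions) to a count.
    """
    by_group: dict[tuple, list] = {}
    for fam in families:
        by_group.setdefault(tuple(fam.models), []).append(fam)

    def rep_reads(fam):
        if total_reads is None:
            return 0.0
        return float(total_reads.get(fam.representative, 0.0))

    selections = []
    for group in sorted(by_group):
        fams = sorted(by_group[group], key=lambda f: (-rep_reads(f), f.representative))
        want = top_n if isinstance(top_n, int) else top_n.get(group, 0)
        if want > len(fams):
            warnings.warn(
                f"requested {want} candidates for model group {group} but only "
                f"{len(fams)} families exist",
                stacklevel=2,
            )
            want = len(fams)
        for fam in fams[:want]:
            selections.append(CandidateSelection(fam.representative, fam))
    return selections
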