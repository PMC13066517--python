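"""Synthetic two-cohort aptamer-library sequencing data with known ground truth.

The generator emulates the data structure produced by one round of branched
selection of an enriched RNA library against individual milk samples: a set
of "ancestor" variable regions (36-mers over A/C/G/U by default) with
log-normal baseline abundances, per-sample latent proportions perturbed by
planted condition effects (sampling time, BMI group, parity) and per-cell
biological noise, multinomial read sampling at a Poisson per-sample depth,
and per-read edit noise (substitution / insertion / deletion / adjacent
transposition) that creates the low-abundance derived sequences the
family-joining stage is designed to collapse.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import dl_distance, encode_many, nearest_within

RNA_ALPHABET = "ACGU"
TIMEPOINTS = ("3d", "1m", "2m", "3m")
CONDITIONS = ("sampling_time", "bmi_group", "parity")

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "GroundTruth",
    "generate_library",
    "generate_cohort",
    "write_fastq",
    "rna_to_dna",
    "dna_to_rna",
]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


@dataclass(frozen=True)
class PlantedEffect:
    """A condition-specific multiplicative effect on latent proportions.

    ``fold_change`` multiplies the latent proportion of the listed ancestor
    sequences in samples belonging to ``study_level`` of ``condition``
    (before compositional renormalization).  ``biological_sigma`` adds extra
    log-normal noise to those sequences in study-group samples only.
    """

    condition: str
    study_level: str
    sequence_indices: tuple
    fold_change: float
    biological_sigma: float = 0.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        object.__setattr__(self, "sequence_indices", tuple(self.sequence_indices))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the discovery-cohort design (participants sampled at
    3 days and 1, 2 and 3 months postpartum; binary BMI group split at
    25 kg/m2; parity split 50/50) at desk scale: 10^5 reads per sample
    rather than millions.
    """

    n_ancestors: int = 1000
    seq_length: int = 36
    alphabet: str = RNA_ALPHABET
    n_participants: int = 86
    timepoints: tuple = TIMEPOINTS
    p_elevated_bmi: float = 0.5
    p_primiparous: float = 0.5
    depth_mean: float = 100_000.0
    abundance_sigma: float = 1.0
    biological_sigma: float = 0.3
    planted: tuple = ()
    mutation_rate: float = 0.02
    max_edits_per_read: int = 3
    barcode_length: int = 8
    well_separated: bool = False
    balanced_groups: bool = False
    cohort: str = "discovery"
    seed: int = 0
    # seed of the shared enriched library; defaults to `seed`.  Discovery and
    # validation cohorts of one study use the same library_seed with
    # different cohort seeds.
    library_seed: int | None = None

    def __post_init__(self):
        self.planted = tuple(self.planted)
        for p in (self.p_elevated_bmi, self.p_primiparous, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.seq_length < self.max_edits_per_read:
            raise ValueError("seq_length must be >= max_edits_per_read")
        if self.n_ancestors < 1:
            raise ValueError("need at least one ancestor")
        seen = {}
        for eff in self.planted:
            key = eff.condition
            idx = set(eff.sequence_indices)
            if idx & seen.get(key, set()):
                raise ValueError(
                    f"sequence_indices overlap across effects for {key}"
                )
            seen.setdefault(key, set()).update(idx)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    ancestors: list
    baseline_proportions: np.ndarray
    planted: tuple
    latent_proportions: pd.DataFrame  # ancestors x samples, columns sum to 1
    pre_mutation_counts: pd.DataFrame  # ancestors x samples, integer
    derived_to_ancestor: dict  # derived sequence -> ancestor sequence

    def to_json(self, path) -> None:
        payload = {
            "ancestors": self.ancestors,
            "baseline_proportions": self.baseline_proportions.tolist(),
            "planted": [asdict(p) for p in self.planted],
            "latent_proportions": {
                c: self.latent_proportions[c].tolist()
                for c in self.latent_proportions.columns
            },
            "derived_to_ancestor": self.derived_to_ancestor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_library(
    config: SimulationConfig, *, d_max: int = 3, max_attempts: int = 200
):
    """Draw the ancestor library and its baseline abundance distribution.

    Returns ``(ancestors, baseline_proportions)``.  Baselines are normalized
    exp(Normal(0, abundance_sigma)) draws.  With ``well_separated`` set,
    ancestors are rejection-sampled until all pairwise Damerau-Levenshtein
    distances exceed ``2 * d_max``, so that no derived read can sit within
    ``d_max`` of a foreign ancestor.
    """
    lib_seed = config.seed if config.library_seed is None else config.library_seed
    rng = np.random.default_rng(lib_seed)
    alphabet = list(config.alphabet)
    n, L = config.n_ancestors, config.seq_length

    seqs: list[str] = []
    if not config.well_separated:
        seen = set()
        while len(seqs) < n:
            s = "".join(rng.choice(alphabet, size=L))
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    else:
        min_sep = 2 * d_max + 1
        reps = np.zeros((n, L), dtype=np.uint8)
        lens = np.full(n, L, dtype=np.int64)
        while len(seqs) < n:
            for _ in range(max_attempts):
                s = "".join(rng.choice(alphabet, size=L))
                q = np.frombuffer(s.encode(), dtype=np.uint8)
                idx, _ = nearest_within(q, L, reps, lens, len(seqs), min_sep - 1)
                if idx == -1:
                    reps[len(seqs)] = q
                    seqs.append(s)
                    break
            else:
                raise RuntimeError(
                    f"could not place {n} ancestors of length {L} with pairwise "
                    f"distance > {2 * d_max} after {max_attempts} attempts each"
                )

    log_abund = rng.normal(0.0, config.abundance_sigma, size=n)
    w = np.exp(log_abund)
    return seqs, w / w.sum()


def _sample_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    if config.balanced_groups:
        n_elev = int(round(config.p_elevated_bmi * n))
        n_prim = int(round(config.p_primiparous * n))
        elevated = np.zeros(n, dtype=bool)
        elevated[rng.permutation(n)[:n_elev]] = True
        primi = np.zeros(n, dtype=bool)
        primi[rng.permutation(n)[:n_prim]] = True
    else:
        elevated = rng.random(n) < config.p_elevated_bmi
        primi = rng.random(n) < config.p_primiparous
    rows = []
    for i in range(n):
        pid = f"{config.cohort[:1].upper()}P{i + 1:04d}"
        for tp in config.timepoints:
            rows.append(
                {
                    "sample_id": f"{pid}_{tp}",
                    "participant_id": pid,
                    "timepoint": tp,
                    "bmi_group": "elevated" if elevated[i] else "normal",
                    "parity": "primiparous" if primi[i] else "multiparous",
                    "cohort": config.cohort,
                }
            )
    return pd.DataFrame(rows)


def _latent_proportions(
    config: SimulationConfig,
    baseline: np.ndarray,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_seq = len(baseline)
    cols = {}
    for _, row in meta.iterrows():
        w = baseline.astype(float).copy()
        for eff in config.planted:
            if eff.condition == "sampling_time":
                applies = row["timepoint"] == eff.study_level
            else:
                applies = row[eff.condition] == eff.study_level
            if applies:
                idx = list(eff.sequence_indices)
                w[idx] *= eff.fold_change
                if eff.biological_sigma > 0:
                    w[idx] *= np.exp(
                        rng.normal(0.0, eff.biological_sigma, size=len(idx))
                    )
        if config.biological_sigma > 0:
            w *= np.exp(rng.normal(0.0, config.biological_sigma, size=n_seq))
        cols[row["sample_id"]] = w / w.sum()
    return pd.DataFrame(cols)


_EDIT_OPS = ("substitution", "insertion", "deletion", "transposition")


def _mutate(seq: str, n_edits: int, rng: np.random.Generator, alphabet: str) -> str:
    chars = list(seq)
    for _ in range(n_edits):
        op = _EDIT_OPS[rng.integers(0, 4)]
        if op == "substitution" and chars:
            pos = int(rng.integers(0, len(chars)))
            options = [c for c in alphabet if c != chars[pos]]
            chars[pos] = options[rng.integers(0, len(options))]
        elif op == "insertion":
            pos = int(rng.integers(0, len(chars) + 1))
            chars.insert(pos, alphabet[rng.integers(0, len(alphabet))])
        elif op == "deletion" and len(chars) > 1:
            pos = int(rng.integers(0, len(chars)))
            del chars[pos]
        elif op == "transposition" and len(chars) >= 2:
            pos = int(rng.integers(0, len(chars) - 1))
            chars[pos], chars[pos + 1] = chars[pos + 1], chars[pos]
    return "".join(chars)


def generate_cohort(config: SimulationConfig):
    """Simulate one cohort end to end.

    Returns ``(counts, metadata, truth)`` where ``counts`` is the observed
    CountMatrix (sequences x samples, integer reads, rows sorted by
    descending total then lexicographic), ``metadata`` the per-sample table,
    and ``truth`` a :class:`GroundTruth`.
    """
    ancestors, baseline = generate_library(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    meta = _sample_metadata(config, rng)
    latent = _latent_proportions(config, baseline, meta, rng)
    latent.index = pd.Index(range(len(ancestors)), name="ancestor_index")

    sample_ids = list(meta["sample_id"])
    depths = rng.poisson(config.depth_mean, size=len(sample_ids))
    depths = np.maximum(depths, 1)

    pre_counts = np.zeros((len(ancestors), len(sample_ids)), dtype=np.int64)
    derived_to_ancestor: dict[str, str] = {}

    if config.mutation_rate == 0:
        for s_idx, sid in enumerate(sample_ids):
            pre_counts[:, s_idx] = rng.multinomial(
                depths[s_idx], latent[sid].to_numpy()
            )
        observed_rows = pre_counts.sum(axis=1) > 0
        counts = pd.DataFrame(
            pre_counts[observed_rows],
            index=pd.Index(
                [a for a, keep in zip(ancestors, observed_rows) if keep],
                name="sequence",
            ),
            columns=sample_ids,
        )
    else:
        observed: dict[str, dict[str, int]] = {}
        for s_idx, sid in enumerate(sample_ids):
            draws = rng.multinomial(depths[s_idx], latent[sid].to_numpy())
            pre_counts[:, s_idx] = draws
            tallies = observed.setdefault(sid, {})
            for a_idx in np.nonzero(draws)[0]:
                n_reads = int(draws[a_idx])
                anc = ancestors[a_idx]
                n_mut = rng.binomial(n_reads, config.mutation_rate)
                if n_reads - n_mut:
                    tallies[anc] = tallies.get(anc, 0) + (n_reads - n_mut)
                for _ in range(n_mut):
                    n_edits = int(rng.integers(1, config.max_edits_per_read + 1))
                    mutant = _mutate(anc, n_edits, rng, config.alphabet)
                    tallies[mutant] = tallies.get(mutant, 0) + 1
                    if mutant != anc and mutant not in derived_to_ancestor:
                        derived_to_ancestor[mutant] = anc
        all_seqs = sorted({s for t in observed.values() for s in t})
        counts = pd.DataFrame(
            {sid: [observed[sid].get(s, 0) for s in all_seqs] for sid in sample_ids},
            index=pd.Index(all_seqs, name="sequence"),
            dtype=np.int64,
        )
    order = counts.sum(axis=1)
    counts = counts.loc[
        sorted(counts.index, key=lambda s: (-order[s], s))
    ]

    truth = GroundTruth(
        ancestors=list(ancestors),
        baseline_proportions=baseline,
        planted=config.planted,
        latent_proportions=latent,
        pre_mutation_counts=pd.DataFrame(
            pre_counts, index=pd.Index(ancestors, name="sequence"), columns=sample_ids
        ),
        derived_to_ancestor=derived_to_ancestor,
    )
    return counts, meta, truth


def default_barcodes(n: int, length: int = 8, seed: int = 7) -> list[str]:
    """Deterministic distinct DNA barcodes for n samples."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    seen = set()
    while len(codes) < n:
        c = "".join(rng.choice(list("ACGT"), size=length))
        if c not in seen:
            seen.add(c)
            codes.append(c)
    return codes


def write_fastq(
    counts: pd.DataFrame,
    barcodes: dict,
    flank5: str,
    flank3: str,
    path,
) -> int:
    """Emit one FASTQ record per read: barcode + 5' flank + region + 3' flank.

    The variable region is exported on the DNA alphabet (U -> T); qualities
    are dummy 'I'.  Returns the number of records written.  Round-trips
    through :func:`aptaprofile.io.demultiplex` to the identical CountMatrix.
    """
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcodes")
    missing = set(counts.columns) - set(barcodes)
    if missing:
        raise ValueError(f"no barcode for samples: {sorted(missing)}")
    n = 0
    with open(path, "w") as fh:
        for sid in counts.columns:
            bc = rna_to_dna(barcodes[sid]).upper()
            for seq, c in counts[sid].items():
                if c <= 0:
                    continue
                insert = bc + rna_to_dna(flank5) + rna_to_dna(str(seq)) + rna_to_dna(flank3)
                qual = "I" * len(insert)
                for r in range(int(c)):
                    fh.write(f"@{sid}:{seq}:{r}\n{insert}\n+\n{qual}\n")
                    n += 1
    return n
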