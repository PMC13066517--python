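"""Reading, writing and demultiplexing of the pipeline's file formats.

Conventions
-----------
* Count tables are TSV with a first column ``sequence`` and one integer
  column per sample.  Rows are ordered by descending total count, ties
  broken lexicographically, so all outputs are byte-stable.
* Sequences are stored uppercase on the RNA alphabet (T is normalized to
  U on input); FASTQ/FASTA exports use DNA (U -> T).
* Metadata is TSV with columns ``sample_id, participant_id, timepoint,
  bmi_group, parity, cohort`` plus optional extra covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import dna_to_rna, rna_to_dna

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "timepoint",
    "bmi_group",
    "parity",
    "cohort",
)

__all__ = [
    "DemuxStats",
    "demultiplex",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "write_panel_fasta",
    "read_panel_fasta",
    "sort_count_rows",
    "check_samples_match",
]


def sort_count_rows(counts: pd.DataFrame) -> pd.DataFrame:
    """Order rows by descending total count, ties lexicographic."""
    totals = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda s: (-totals[s], s))
    return counts.loc[order]


def _normalize_index(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.copy()
    counts.index = pd.Index(
        [dna_to_rna(str(s).upper()) for s in counts.index], name="sequence"
    )
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    out = sort_count_rows(_normalize_index(counts))
    out.to_csv(path, sep="\t", index_label="sequence")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sequence")
    df = _normalize_index(df)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate sequence rows: {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return sort_count_rows(df.astype("int64"))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dupes[:5]}")
    return meta


def check_samples_match(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Hard check that the counts' samples and the metadata agree."""
    in_counts = set(counts.columns)
    in_meta = set(meta["sample_id"])
    only_counts = sorted(in_counts - in_meta)
    only_meta = sorted(in_meta - in_counts)
    if only_counts or only_meta:
        raise ValueError(
            "sample sets differ between counts and metadata; "
            f"only in counts: {only_counts[:10]}; only in metadata: {only_meta[:10]}"
        )


def write_panel_fasta(sequences, path) -> None:
    """Export a sequence panel as DNA FASTA with stable sorted IDs."""
    seqs = sorted({dna_to_rna(str(s).upper()) for s in sequences})
    records = [
        SeqRecord(Seq(rna_to_dna(s)), id=f"seq{i + 1:04d}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, path, "fasta")


def read_panel_fasta(path) -> list:
    return [dna_to_rna(str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


@dataclass
class DemuxStats:
    total: int = 0
    assigned: int = 0
    unassigned_barcode: int = 0
    failed_structure: int = 0
    per_sample: dict = field(default_factory=dict)

    @property
    def unassigned(self) -> int:
        return self.unassigned_barcode + self.failed_structure


def _match_barcode(code: str, lookup: dict, by_mismatch, max_mismatches: int):
    hit = lookup.get(code)
    if hit is not None or max_mismatches == 0:
        return hit
    candidates = {
        sid
        for bc, sid in by_mismatch
        if sum(a != b for a, b in zip(code, bc)) <= max_mismatches
    }
    if len(candidates) == 1:
        return candidates.pop()
    return None  # ambiguous or no hit


def demultiplex(
    fastq_path,
    barcodes: dict,
    flank5: str = "",
    flank3: str = "",
    *,
    max_mismatches: int = 0,
    sample_ids=None,
):
    """Assign barcoded reads to samples and tally variable regions.

    Reads are matched by exact barcode prefix by default (``max_mismatches``
    up to 1 is supported; ambiguous hits go to the unassigned bucket), then
    the constant flanks are stripped by exact prefix/suffix match.  Returns
    ``(counts, stats)``; ``counts`` has one column per barcode's sample
    (samples with zero reads retained as all-zero columns).
    """
    bcs = list(barcodes.values())
    if len(set(bcs)) != len(bcs):
        raise ValueError("barcodes must be unique")
    if len({len(b) for b in bcs}) > 1:
        raise ValueError("barcodes must have equal length")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    bc_len = len(bcs[0])
    f5 = rna_to_dna(flank5).upper()
    f3 = rna_to_dna(flank3).upper()
    lookup = {rna_to_dna(bc).upper(): sid for sid, bc in barcodes.items()}
    by_mismatch = list(lookup.items())

    tallies: dict[str, dict[str, int]] = {sid: {} for sid in barcodes}
    stats = DemuxStats(per_sample={sid: 0 for sid in barcodes})
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        stats.total += 1
        read = str(rec.seq).upper()
        sid = _match_barcode(read[:bc_len], lookup, by_mismatch, max_mismatches)
        if sid is None:
            stats.unassigned_barcode += 1
            continue
        body = read[bc_len:]
        if not body.startswith(f5) or not body.endswith(f3) or len(body) <= len(f5) + len(f3):
            stats.failed_structure += 1
            continue
        region = body[len(f5): len(body) - len(f3)] if f3 else body[len(f5):]
        region = dna_to_rna(region)
        t = tallies[sid]
        t[region] = t.get(region, 0) + 1
        stats.assigned += 1
        stats.per_sample[sid] += 1
    if stats.total and stats.assigned == 0:
        warnings.warn("no reads were assigned to any sample", stacklevel=2)

    cols = sample_ids if sample_ids is not None else list(barcodes)
    all_seqs = sorted({s for t in tallies.values() for s in t})
    counts = pd.DataFrame(
        {sid: [tallies[sid].get(s, 0) for s in all_seqs] for sid in cols},
        index=pd.Index(all_seqs, name="sequence"),
        dtype="int64",
    )
    return sort_count_rows(counts), stats
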