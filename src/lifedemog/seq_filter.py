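"""Transcriptome decontamination and count pre-filtering.

De novo assemblies of cultured zooplankton inevitably contain transcripts
from the food algae carried along in every sample.  The decontamination
rule implemented here assigns each assembled contig competitively, from
blastn hits against one target genome and one or more competitor
(algal) databases:

* **target** — the top hit is to the target database AND the bit-score
  gain of the best target hit over the best competitor hit is strictly
  greater than the threshold (default 100);
* **contaminant** — the best competitor hit is at least as good as the
  best target hit (a tie means the top hit is not uniquely the target);
* **ambiguous** — the target is the top hit but the gain does not exceed
  the threshold;
* **unassigned** — the contig has no hits at all.

Contigs hitting an rRNA database (18S/28S reference sequences) below an
e-value ceiling are flagged and removed before assignment.  A separate
utility applies the low-count gene pre-filter used ahead of differential
expression: keep a gene only if its total count reaches ``min_count``
and it is non-zero in at least ``min_replicates`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "HitTable",
    "ContigAssignment",
    "assign_contigs",
    "flag_rrna",
    "partition_fasta",
    "filter_low_counts",
    "read_hit_table",
    "read_count_matrix",
    "SeqFilterError",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

CLASSES = ("target", "contaminant", "ambiguous", "unassigned", "rrna")


class SeqFilterError(ValueError):
    pass


@dataclass(frozen=True)
class HitTable:
    """Alignment hits plus the subject -> database label mapping.

    ``labels`` must cover every subject appearing in ``hits``; exactly
    one database label is the target, the rest are competitors, with an
    optional rRNA label handled separately.
    """

    hits: pd.DataFrame
    labels: Mapping[str, str]
    target_label: str
    rrna_label: str | None = None

    def __post_init__(self) -> None:
        missing = set(OUTFMT6_COLUMNS) - set(self.hits.columns)
        if missing:
            raise SeqFilterError(f"hit table missing columns: {sorted(missing)}")
        if (self.hits["bitscore"] < 0).any():
            raise SeqFilterError("bit-scores must be non-negative")
        unlabeled = set(self.hits["sseqid"]) - set(self.labels)
        if unlabeled:
            raise SeqFilterError(
                f"{len(unlabeled)} subject id(s) lack a database label, "
                f"e.g. {sorted(unlabeled)[:3]}"
            )
        if self.target_label not in set(self.labels.values()) and len(self.hits):
            # a target label with no hits at all is legal (everything contaminant)
            pass

    def database_of(self) -> pd.Series:
        """Database label per hit row."""
        return self.hits["sseqid"].map(dict(self.labels))


@dataclass(frozen=True)
class ContigAssignment:
    """Exclusive class per contig with the supporting bit-score margin."""

    frame: pd.DataFrame  # columns: contig_id, assigned_class, margin

    def __post_init__(self) -> None:
        if self.frame["contig_id"].duplicated().any():
            raise SeqFilterError("duplicate contig in assignment")
        bad = set(self.frame["assigned_class"]) - set(CLASSES)
        if bad:
            raise SeqFilterError(f"unknown classes: {sorted(bad)}")

    def classes(self) -> pd.Series:
        return self.frame.set_index("contig_id")["assigned_class"]

    def counts(self) -> pd.Series:
        return self.frame["assigned_class"].value_counts().reindex(
            CLASSES, fill_value=0
        )


def flag_rrna(table: HitTable, evalue_ceiling: float = 1e-10) -> set[str]:
    """Contigs with at least one rRNA-database hit at e-value <= ceiling."""
    if table.rrna_label is None or table.hits.empty:
        return set()
    db = table.database_of()
    mask = (db == table.rrna_label) & (table.hits["evalue"] <= evalue_ceiling)
    return set(table.hits.loc[mask, "qseqid"])


def assign_contigs(
    table: HitTable,
    gain_threshold: float = 100.0,
    *,
    all_contigs: Sequence[str] | None = None,
    rrna_evalue_ceiling: float = 1e-10,
) -> ContigAssignment:
    """Competitively assign contigs by best-hit bit-score gain.

    For each contig let ``B_t`` be the best bit-score against the target
    database and ``B_c`` the best against any competitor (0 when
    absent).  The contig is *target* iff ``B_t > B_c`` and
    ``B_t - B_c > gain_threshold`` (strict), *contaminant* iff
    ``B_c >= B_t``, *ambiguous* otherwise.  Contigs flagged as rRNA are
    classed ``rrna`` regardless of other hits; contigs in
    ``all_contigs`` without any hit are ``unassigned``.
    """
    rrna_ids = flag_rrna(table, rrna_evalue_ceiling)
    hits = table.hits
    db = table.database_of()

    rows = []
    seen: set[str] = set()
    if not hits.empty:
        non_rrna = hits[db != table.rrna_label] if table.rrna_label else hits
        db_nr = (
            non_rrna["sseqid"].map(dict(table.labels))
            if len(non_rrna)
            else pd.Series(dtype=object)
        )
        for contig, sub in non_rrna.groupby("qseqid", sort=True):
            seen.add(contig)
            if contig in rrna_ids:
                continue
            sub_db = db_nr.loc[sub.index]
            target_mask = sub_db == table.target_label
            b_t = float(sub.loc[target_mask, "bitscore"].max()) if target_mask.any() else 0.0
            b_c = float(sub.loc[~target_mask, "bitscore"].max()) if (~target_mask).any() else 0.0
            margin = b_t - b_c
            if not target_mask.any() and not (~target_mask).any():
                cls = "unassigned"
            elif b_c >= b_t:
                cls = "contaminant"
            elif margin > gain_threshold:
                cls = "target"
            else:
                cls = "ambiguous"
            rows.append((contig, cls, margin))
    for contig in sorted(rrna_ids):
        rows.append((contig, "rrna", float("nan")))
        seen.add(contig)
    if all_contigs is not None:
        ids = list(all_contigs)
        if len(set(ids)) != len(ids):
            raise SeqFilterError("duplicate contig ids")
        for contig in ids:
            if contig not in seen:
                rows.append((contig, "unassigned", float("nan")))
    frame = pd.DataFrame(rows, columns=["contig_id", "assigned_class", "margin"])
    frame = frame.sort_values("contig_id", kind="stable").reset_index(drop=True)
    return ContigAssignment(frame=frame)


def partition_fasta(
    fasta_path,
    assignment: ContigAssignment,
    out_dir,
) -> dict[str, int]:
    """Split a contig FASTA into one file per assigned class.

    Sequence ids absent from the assignment are treated as unassigned.
    Returns per-class sequence counts (conserving the input total).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classes = assignment.classes()
    records = {cls: [] for cls in CLASSES}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise SeqFilterError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        cls = classes.get(rec.id, "unassigned")
        records[cls].append(rec)
    counts = {}
    for cls in CLASSES:
        path = out_dir / f"{cls}.fasta"
        SeqIO.write(records[cls], str(path), "fasta")
        counts[cls] = len(records[cls])
    return counts


def filter_low_counts(
    counts: pd.DataFrame,
    min_count: int = 10,
    min_replicates: int = 2,
    *,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Remove low-count genes before differential-expression modelling.

    A gene is retained iff its total count across samples is at least
    ``min_count`` (or, with ``per_sample=True``, some single sample
    reaches ``min_count``) AND it is non-zero in at least
    ``min_replicates`` samples.  The output is a row subset of the
    input; applying the filter twice changes nothing.
    """
    if (counts.values < 0).any():
        raise SeqFilterError("count matrix contains negative entries")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise SeqFilterError("gene and sample ids must be unique")
    if per_sample:
        abundant = (counts >= min_count).any(axis=1)
    else:
        abundant = counts.sum(axis=1) >= min_count
    replicated = (counts > 0).sum(axis=1) >= min_replicates
    return counts.loc[abundant & replicated]


# ---------------------------------------------------------------------------
# file IO

def read_hit_table(
    hits_path,
    labels_path,
    target_label: str,
    rrna_label: str | None = None,
) -> HitTable:
    """Read a headerless outfmt-6 TSV plus the sseqid -> database sidecar."""
    hits = pd.read_csv(hits_path, sep="\t", names=OUTFMT6_COLUMNS, header=None)
    if len(hits) and hits.iloc[0, 0] == "qseqid":  # tolerate a header row
        hits = hits.iloc[1:].reset_index(drop=True)
        hits = hits.astype({"evalue": float, "bitscore": float})
    labels_frame = pd.read_csv(labels_path, sep="\t")
    if set(labels_frame.columns) >= {"sseqid", "database"}:
        labels = dict(zip(labels_frame["sseqid"], labels_frame["database"]))
    else:
        labels = dict(zip(labels_frame.iloc[:, 0], labels_frame.iloc[:, 1]))
    return HitTable(hits=hits, labels=labels, target_label=target_label,
                    rrna_label=rrna_label)


def read_count_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene_id"
    return matrix
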