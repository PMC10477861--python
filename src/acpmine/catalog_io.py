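"""Peptide catalog handling.

A *catalog* is an ordered, id-unique collection of peptide records — a
candidate pool mined from metagenomes, or a reference set of published
anticancer/antimicrobial peptides. This module reads and writes catalogs as
FASTA, removes entries with non-natural residues, merges catalogs with exact
-sequence deduplication, cross-tabulates overlap between sets, and summarizes
cell-line growth-inhibition screens of synthesized candidates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetic_code import CANONICAL_AA_SET

__all__ = [
    "PeptideRecord",
    "PeptideCatalog",
    "OverlapStats",
    "ScreenSummary",
    "read_fasta",
    "write_fasta",
    "filter_natural_aa",
    "deduplicate_union",
    "overlap_stats",
    "recall_rate",
    "summarize_screen",
]


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence with provenance labels."""

    id: str
    sequence: str
    source_db: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideCatalog:
    """Ordered collection of :class:`PeptideRecord` with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate peptide id {rec.id!r} in catalog")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, peptide_id: str) -> PeptideRecord:
        for rec in self.records:
            if rec.id == peptide_id:
                return rec
        raise KeyError(peptide_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


@dataclass(frozen=True)
class OverlapStats:
    """Exact-sequence overlap between two peptide sets.

    ``overlap_pct`` is the share of the deduplicated union that occurs in
    both sets, reported to one decimal.
    """

    n_a: int
    n_b: int
    n_union_unique: int
    n_overlap: int
    overlap_pct: float

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ScreenSummary:
    """Summary of a growth-inhibition screen over a cell-line panel."""

    n_peptides: int
    n_active: int
    active_pct: float
    per_peptide_hits: "pd.Series"

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.per_peptide_hits.rename("n_cell_lines_inhibited").to_frame()
        df.insert(0, "peptide_id", df.index)
        df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | os.PathLike, name: str = "", source_db: Optional[str] = None) -> PeptideCatalog:
    """Read a peptide FASTA into a catalog.

    Ids are the header token before the first whitespace; sequences are
    uppercased. Duplicate ids and empty sequences are errors.
    """
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise ValueError(f"{path}: not FASTA — first non-blank line does not start with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(PeptideRecord(id=rec.id, sequence=seq, source_db=source_db))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return PeptideCatalog(records=records, name=name or os.path.basename(str(path)))


def write_fasta(catalog: PeptideCatalog, path: str | os.PathLike) -> None:
    """Write a catalog as FASTA, wrapped at 60 columns."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in catalog]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)


def filter_natural_aa(catalog: PeptideCatalog) -> tuple[PeptideCatalog, list[str]]:
    """Drop records containing residues outside the 20 canonical amino acids.

    Returns the filtered catalog and the ids that were removed (B, J, O, U,
    X and Z all count as non-natural).
    """
    kept, removed = [], []
    for rec in catalog:
        if set(rec.sequence) <= CANONICAL_AA_SET:
            kept.append(rec)
        else:
            removed.append(rec.id)
    return PeptideCatalog(records=kept, name=catalog.name), removed


def deduplicate_union(catalog_a: PeptideCatalog, catalog_b: PeptideCatalog,
                      name: str = "union") -> PeptideCatalog:
    """Union of two catalogs keyed on exact sequence equality.

    The first-seen record for each distinct sequence is kept, in input order
    (all of ``catalog_a`` before ``catalog_b``), so the result is
    deterministic and idempotent.
    """
    seen_seq: set[str] = set()
    seen_id: set[str] = set()
    out: list[PeptideRecord] = []
    for rec in list(catalog_a) + list(catalog_b):
        if rec.sequence in seen_seq:
            continue
        seen_seq.add(rec.sequence)
        rid = rec.id
        # distinct sequences may reuse an id across catalogs; keep ids unique
        if rid in seen_id:
            suffix = 2
            while f"{rid}.{suffix}" in seen_id:
                suffix += 1
            rid = f"{rid}.{suffix}"
            rec = PeptideRecord(id=rid, sequence=rec.sequence,
                                source_db=rec.source_db, species=rec.species)
        seen_id.add(rid)
        out.append(rec)
    return PeptideCatalog(records=out, name=name)


def overlap_stats(catalog_a: PeptideCatalog, catalog_b: PeptideCatalog) -> OverlapStats:
    """Exact-sequence overlap of two sets over their deduplicated union."""
    seqs_a = set(catalog_a.sequences)
    seqs_b = set(catalog_b.sequences)
    union = seqs_a | seqs_b
    if not union:
        raise ValueError("overlap undefined: union of the two catalogs is empty")
    overlap = seqs_a & seqs_b
    return OverlapStats(
        n_a=len(catalog_a),
        n_b=len(catalog_b),
        n_union_unique=len(union),
        n_overlap=len(overlap),
        overlap_pct=round(100.0 * len(overlap) / len(union), 1),
    )


def recall_rate(recalled: int, pool: int) -> float:
    """Percentage of a reference pool recovered, to two decimals."""
    if pool <= 0:
        raise ValueError("pool must be positive")
    if not 0 <= recalled <= pool:
        raise ValueError("recalled must lie in [0, pool]")
    return round(100.0 * recalled / pool, 2)


def summarize_screen(survival_pct_table: pd.DataFrame,
                     inhibition_threshold_pct: float = 20.0) -> ScreenSummary:
    """Summarize a cell-viability screen.

    ``survival_pct_table`` holds percent survival (peptides as rows, cell
    lines as columns). A peptide is *active* if its growth inhibition,
    ``100 - survival``, reaches the threshold in at least one cell line.
    """
    if survival_pct_table.empty:
        raise ValueError("empty screen table")
    if not 0 < inhibition_threshold_pct < 100:
        raise ValueError("inhibition threshold must lie in (0, 100)")
    vals = survival_pct_table.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("survival values must lie in [0, 100]")
    hits = ((100.0 - survival_pct_table) >= inhibition_threshold_pct).sum(axis=1)
    n_pep = len(survival_pct_table)
    n_active = int((hits >= 1).sum())
    return ScreenSummary(
        n_peptides=n_pep,
        n_active=n_active,
        active_pct=round(100.0 * n_active / n_pep, 1),
        per_peptide_hits=hits.astype(int),
    )
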