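"""Protein-space read mapping and coverage-per-million profiling.

Short metagenomic DNA reads are translated in all six frames, fragments are
seeded against a peptide catalog via exact amino-acid k-mers and extended
without gaps under a substitution matrix; each read is assigned to at most
one peptide (highest-scoring valid span, ties to the lexicographically
smallest peptide id). Per-sample abundance is reported as CPM — mapped-read
count per million total sequenced reads:

    CPM(peptide, sample) = mapped_reads(peptide, sample) * 1e6 / total_reads(sample)

``map_read`` is the plain-Python reference mapper; ``profile_abundance``
dispatches whole samples to a compiled batch kernel with identical
semantics (the test suite asserts their agreement), which is what makes
cohort-scale profiling practical on one CPU.

A *valid span* for read fragment f and peptide p is any ungapped pairing of
equal-length windows with length >= ``min_match_len`` and identity >=
``min_identity``; a candidate's score is the best substitution-matrix sum
over its valid spans.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from ._genetic_code import (
    STOP_CODE,
    blosum62,
    codon_code_table,
    decode_protein,
    encode_dna,
    encode_protein,
    reverse_complement,
)
from .catalog_io import PeptideCatalog

__all__ = [
    "MappingParams",
    "SampleReads",
    "AbundanceMatrix",
    "KmerIndex",
    "translate_six_frames",
    "build_kmer_index",
    "map_read",
    "profile_abundance",
    "read_sample_sheet",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("control", "case")


@dataclass(frozen=True)
class MappingParams:
    """Tunables of the protein-space mapper.

    Defaults are chosen so that exact peptide-coding reads always map while
    uniform-random 100-nt reads map with negligible probability.
    """

    kmer_size: int = 4
    min_match_len: int = 8
    min_identity: float = 0.9
    substitution_matrix: str = "BLOSUM62"
    min_orf_len: int = 8

    def __post_init__(self) -> None:
        if self.kmer_size < 3:
            raise ValueError("kmer_size must be >= 3")
        if self.kmer_size > self.min_match_len:
            raise ValueError("kmer_size must not exceed min_match_len")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.substitution_matrix != "BLOSUM62":
            raise ValueError("only BLOSUM62 is supported")

    @property
    def matrix(self) -> np.ndarray:
        return blosum62()


def _frame_codes(codes: np.ndarray, min_orf_len: int) -> list[np.ndarray]:
    """Encoded >=min_orf_len fragments of all six frames of one read."""
    table = codon_code_table()
    frags: list[np.ndarray] = []
    for strand in (codes, reverse_complement(codes)):
        for frame in range(3):
            n_codons = (len(strand) - frame) // 3
            if n_codons <= 0:
                continue
            trimmed = strand[frame:frame + 3 * n_codons].reshape(-1, 3).astype(np.int64)
            aa = table[25 * trimmed[:, 0] + 5 * trimmed[:, 1] + trimmed[:, 2]]
            # split at stops and X (anything >= STOP_CODE)
            breaks = np.flatnonzero(aa >= STOP_CODE)
            start = 0
            for b in list(breaks) + [len(aa)]:
                if b - start >= min_orf_len:
                    frags.append(aa[start:b].astype(np.uint8))
                start = b + 1
    return frags


def translate_six_frames(read: str, min_orf_len: int = 8) -> list[str]:
    """Translate a DNA read in all six frames into peptide fragments.

    Fragments are split at stop codons and at ``X`` residues (any codon
    containing ``N``); only fragments of at least ``min_orf_len`` residues
    are returned. A read too short to yield any fragment gives an empty
    list.
    """
    codes = encode_dna(read)
    return [decode_protein(f) for f in _frame_codes(codes, min_orf_len)]


@dataclass
class KmerIndex:
    """Exact amino-acid k-mer index over a catalog.

    Maps each k-mer to its postings — ``(peptide_id, offset)`` pairs in
    catalog order.
    """

    kmer_size: int
    postings: dict[str, list[tuple[str, int]]]


def build_kmer_index(catalog: PeptideCatalog, kmer_size: int) -> KmerIndex:
    if kmer_size < 3:
        raise ValueError("kmer_size must be >= 3")
    postings: dict[str, list[tuple[str, int]]] = {}
    for rec in catalog:
        if len(rec.sequence) < kmer_size:
            logger.warning("peptide %s shorter than k=%d; excluded from index",
                           rec.id, kmer_size)
            continue
        for off in range(len(rec.sequence) - kmer_size + 1):
            postings.setdefault(rec.sequence[off:off + kmer_size], []).append((rec.id, off))
    return KmerIndex(kmer_size=kmer_size, postings=postings)


def _best_span_score(frag: np.ndarray, pep: np.ndarray, diag: int,
                     min_match_len: int, min_identity: float,
                     sub: np.ndarray) -> Optional[int]:
    """Best substitution score over valid spans on one ungapped diagonal."""
    i0 = max(0, diag)
    j0 = max(0, -diag)
    lo = min(len(frag) - i0, len(pep) - j0)
    if lo < min_match_len:
        return None
    fseg = frag[i0:i0 + lo].astype(np.int64)
    pseg = pep[j0:j0 + lo].astype(np.int64)
    pm = np.concatenate(([0], np.cumsum(fseg == pseg)))
    ps = np.concatenate(([0], np.cumsum(sub[fseg, pseg])))
    best: Optional[int] = None
    for st in range(lo - min_match_len + 1):
        for en in range(st + min_match_len, lo + 1):
            span = en - st
            if pm[en] - pm[st] >= min_identity * span - 1e-9:
                sc = int(ps[en] - ps[st])
                if best is None or sc > best:
                    best = sc
    return best


def map_read(read: str, index: KmerIndex, catalog: PeptideCatalog,
             params: Optional[MappingParams] = None) -> Optional[str]:
    """Map one DNA read to its best-hit peptide, or ``None``.

    Reference implementation: translated fragments are seeded by exact
    k-mer matches, candidate diagonals are scored ungapped, and the
    highest-scoring peptide wins (lexicographic tie-break).
    """
    params = params or MappingParams()
    if index.kmer_size != params.kmer_size:
        raise ValueError("index kmer size does not match params.kmer_size")
    sub = params.matrix
    k = params.kmer_size
    pep_codes = {rec.id: encode_protein(rec.sequence) for rec in catalog}
    best: Optional[tuple[int, str]] = None
    for frag in _frame_codes(encode_dna(read), params.min_orf_len):
        fstr = decode_protein(frag)
        diags: set[tuple[str, int]] = set()
        for i in range(len(fstr) - k + 1):
            for pid, off in index.postings.get(fstr[i:i + k], ()):
                diags.add((pid, i - off))
        for pid, diag in diags:
            sc = _best_span_score(frag, pep_codes[pid], diag,
                                  params.min_match_len, params.min_identity, sub)
            if sc is None:
                continue
            if best is None or sc > best[0] or (sc == best[0] and pid < best[1]):
                best = (sc, pid)
    return None if best is None else best[1]


class SampleReads:
    """Reads of one metagenomic sample with its case/control label.

    Reads are held either as strings or as an encoded (matrix, lengths)
    pair; ``total_reads`` always equals the number of reads supplied.
    """

    def __init__(self, sample_id: str, group: str,
                 reads: Optional[Sequence[str]] = None,
                 matrix: Optional[np.ndarray] = None,
                 lengths: Optional[np.ndarray] = None):
        if group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}, got {group!r}")
        self.sample_id = sample_id
        self.group = group
        if matrix is not None:
            if lengths is None:
                lengths = np.full(matrix.shape[0], matrix.shape[1], dtype=np.int64)
            self._matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
            self._lengths = np.asarray(lengths, dtype=np.int64)
            self._reads: Optional[list[str]] = None
            self.total_reads = int(matrix.shape[0])
        elif reads is not None:
            self._reads = list(reads)
            self._matrix = None
            self._lengths = None
            self.total_reads = len(self._reads)
        else:
            raise ValueError("provide reads or an encoded matrix")

    @classmethod
    def from_path(cls, sample_id: str, group: str, path: str | os.PathLike) -> "SampleReads":
        """Load reads from FASTA or FASTQ (quality ignored)."""
        from Bio import SeqIO

        ext = os.path.splitext(str(path))[1].lower()
        fmt = "fastq" if ext in (".fq", ".fastq") else "fasta"
        reads = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]
        if not reads:
            raise ValueError(f"{path}: no reads found")
        return cls(sample_id=sample_id, group=group, reads=reads)

    def sequences(self) -> Iterator[str]:
        if self._reads is not None:
            yield from self._reads
        else:
            from ._genetic_code import decode_dna

            for i in range(self.total_reads):
                yield decode_dna(self._matrix[i, :self._lengths[i]])

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """Reads as a padded uint8 matrix plus per-read lengths."""
        if self._matrix is not None:
            return self._matrix, self._lengths
        lens = np.array([len(r) for r in self._reads], dtype=np.int64)
        mat = np.full((len(self._reads), int(lens.max(initial=1))), 4, dtype=np.uint8)
        for i, r in enumerate(self._reads):
            mat[i, :len(r)] = encode_dna(r)
        return mat, lens


@dataclass
class AbundanceMatrix:
    """Peptides x samples CPM matrix with per-sample group labels."""

    values: pd.DataFrame            # index: peptide ids, columns: sample ids
    group_labels: pd.Series         # index: sample ids, values in GROUP_LABELS

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("CPM values must be non-negative")
        if list(self.group_labels.index) != list(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """CPM re-expressed as a fraction of total reads (CPM / 1e6)."""
        return self.values / 1e6

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("peptide_id\t" + "\t".join(self.sample_ids) + "\n")
            fh.write("group\t" + "\t".join(self.group_labels) + "\n")
            self.values.to_csv(fh, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AbundanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            groups = fh.readline().rstrip("\n").split("\t")
            if header[0] != "peptide_id" or groups[0] != "group":
                raise ValueError(f"{path}: not an abundance TSV")
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        df.index.name = "peptide_id"
        df.columns = header[1:]
        return cls(values=df, group_labels=pd.Series(groups[1:], index=header[1:]))


def _count_sample_python(sample: SampleReads, index: KmerIndex,
                         catalog: PeptideCatalog, params: MappingParams) -> np.ndarray:
    order = {pid: i for i, pid in enumerate(catalog.ids)}
    counts = np.zeros(len(catalog), dtype=np.int64)
    for read in sample.sequences():
        hit = map_read(read, index, catalog, params)
        if hit is not None:
            counts[order[hit]] += 1
    return counts


def _count_sample_batch(sample: SampleReads, packed, params: MappingParams) -> np.ndarray:
    from ._mapper_kernel import map_reads_batch

    mat, lens = sample.encoded()
    hits = map_reads_batch(mat, lens, packed, params)
    return np.bincount(hits[hits >= 0], minlength=packed.n_peptides)


def profile_abundance(samples: Sequence[SampleReads], catalog: PeptideCatalog,
                      params: Optional[MappingParams] = None,
                      engine: str = "batch",
                      length_normalize: bool = False) -> AbundanceMatrix:
    """Map every sample's reads against the catalog and return CPM values.

    ``engine="batch"`` uses the compiled kernel (default);
    ``engine="python"`` runs the reference mapper read by read (slow, for
    small inputs and cross-checks). With ``length_normalize=True`` each CPM
    value is additionally divided by the peptide length in residues (a
    per-residue coverage variant; not the default definition).
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if engine not in ("batch", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    params = params or MappingParams()
    cols = {}
    if engine == "python":
        index = build_kmer_index(catalog, params.kmer_size)
        counter = lambda s: _count_sample_python(s, index, catalog, params)
    else:
        from ._mapper_kernel import PackedCatalog

        packed = PackedCatalog.from_catalog(catalog, params.kmer_size)
        counter = lambda s: _count_sample_batch(s, packed, params)
    seen = set()
    for sample in samples:
        if sample.sample_id in seen:
            raise ValueError(f"duplicate sample id {sample.sample_id!r}")
        seen.add(sample.sample_id)
        if sample.total_reads == 0:
            raise ValueError(f"sample {sample.sample_id!r} has zero reads")
        counts = counter(sample)
        cpm = counts * 1e6 / sample.total_reads
        if length_normalize:
            cpm = cpm / np.array([len(r.sequence) for r in catalog], dtype=float)
        cols[sample.sample_id] = cpm
        logger.info("sample %s: %d/%d reads mapped", sample.sample_id,
                    int(counts.sum()), sample.total_reads)
    values = pd.DataFrame(cols, index=catalog.ids)
    values.index.name = "peptide_id"
    groups = pd.Series({s.sample_id: s.group for s in samples})[values.columns]
    return AbundanceMatrix(values=values, group_labels=groups)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, group, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df
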