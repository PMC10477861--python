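"""Synthetic peptide catalogs and two-group cohort metagenomes.

Emulates, at desk scale, a case/control gut-metagenome study in which some
peptide-coding loci differ in abundance between groups: every peptide gets
a log-normal baseline relative abundance; *planted* peptides additionally
carry a group effect of ``2**(+-planted_log2fc/2)`` split symmetrically
between control and case so the overall scale stays group-balanced; each
sample multiplies in its own log-normal biological jitter. Reads are then
either coding reads — random windows of the peptide's reverse-translated
coding sequence with at least ``min_coding_overlap_nt`` of coding overlap,
random strand, random flanks — or uniform-random background DNA.

Background reads are uniform-random rather than drawn from real genomes:
this keeps the package download-free and guarantees near-zero spurious
mapping at the mapper's default identity threshold. The planted truth table
is returned alongside the samples so recovery by the downstream funnel can
be scored exactly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._genetic_code import (
    AA_TO_CODONS,
    CANONICAL_AA,
    encode_dna,
    reverse_complement,
)
from .abundance import AbundanceMatrix, SampleReads
from .catalog_io import PeptideCatalog, PeptideRecord

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_catalog",
    "reverse_translate",
    "simulate_cohort",
    "simulate_null_abundance",
    "evaluate_recovery",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one peptide."""

    peptide_id: str
    planted_log2fc: float   # log2(control/case); 0 for null peptides
    base_abundance: float   # expected fraction of reads before group effect
    is_null: bool


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe the benchmark configuration: 1000 candidate peptides,
    5% planted at |log2FC| = 3 (half control-enriched, half case-enriched),
    30 + 30 samples of 1e5 100-nt reads. Baseline relative abundances are
    LogNormal(ln 3e-4, 0.5) so the total coding fraction sits near 0.35 and
    typical planted control-enriched peptides clear the funnel's default
    2e-4 relative-abundance floor.
    """

    seed: int
    n_peptides: int = 1000
    frac_planted: float = 0.05
    planted_log2fc: float = 3.0
    n_ctrl: int = 30
    n_case: int = 30
    reads_per_sample: int = 100_000
    read_length_nt: int = 100
    abundance_log_mu: float = math.log(3e-4)
    abundance_log_sigma: float = 0.5
    sample_jitter_sigma: float = 0.5
    min_coding_overlap_nt: int = 24

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_peptides", "n_ctrl", "n_case", "reads_per_sample",
                     "read_length_nt"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.frac_planted <= 1:
            raise ValueError("frac_planted must lie in (0, 1]")
        if self.min_coding_overlap_nt > self.read_length_nt:
            raise ValueError("min_coding_overlap_nt cannot exceed the read length")


def generate_catalog(n: int, length_range: tuple[int, int] = (31, 50),
                     seed: int = 0, name: str = "synthetic",
                     id_prefix: str = "pep") -> PeptideCatalog:
    """Uniform-random canonical peptides with lengths uniform in a range."""
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range [{lo}, {hi}]")
    rng = np.random.default_rng([seed, 0])
    width = len(str(n))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(CANONICAL_AA[c] for c in rng.integers(0, 20, size=length))
        records.append(PeptideRecord(id=f"{id_prefix}{i + 1:0{width}d}", sequence=seq,
                                     source_db=name))
    return PeptideCatalog(records=records, name=name)


def _reverse_translate_rng(peptide: str, rng: np.random.Generator) -> str:
    codons = []
    for pos, aa in enumerate(peptide):
        options = AA_TO_CODONS.get(aa)
        if options is None:
            raise ValueError(f"non-canonical residue {aa!r} at position {pos}")
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def reverse_translate(peptide: str, seed: int = 0) -> str:
    """A DNA coding sequence for the peptide with random synonymous codons.

    Translating the result in frame +1 recovers the peptide exactly.
    """
    return _reverse_translate_rng(peptide, np.random.default_rng([seed, 1]))


def _coding_read(row: np.ndarray, cds: np.ndarray, rng: np.random.Generator,
                 read_len: int, min_overlap: int) -> None:
    """Overwrite part of a background row with a window of the coding sequence."""
    lc = len(cds)
    ov = min(min_overlap, lc)
    start = int(rng.integers(-(read_len - ov), lc - ov + 1))
    a = max(0, -start)
    b = min(read_len, lc - start)
    row[a:b] = cds[start + a:start + b]
    if rng.random() < 0.5:
        row[:] = reverse_complement(row)


def simulate_cohort(catalog: PeptideCatalog, config: SimConfig
                    ) -> tuple[list[SampleReads], list[SyntheticTruth]]:
    """Simulate a two-group cohort of read sets over a peptide catalog.

    Returns one :class:`SampleReads` per sample (controls first) and the
    planted truth per peptide. Fully reproducible under ``config.seed``;
    per-sample random streams are derived from the master seed by sample
    index, so samples are independent of each other's order of generation.
    """
    n_pep = len(catalog)
    n_planted = int(round(config.frac_planted * n_pep))
    if n_planted < 1:
        raise ValueError("frac_planted * catalog size must be >= 1")
    rng0 = np.random.default_rng([config.seed, 0])

    planted_idx = rng0.choice(n_pep, size=n_planted, replace=False)
    lfc = np.zeros(n_pep)
    n_up = (n_planted + 1) // 2
    lfc[planted_idx[:n_up]] = config.planted_log2fc      # control-enriched
    lfc[planted_idx[n_up:]] = -config.planted_log2fc     # case-enriched
    base = rng0.lognormal(config.abundance_log_mu, config.abundance_log_sigma,
                          size=n_pep)
    cds = [encode_dna(_reverse_translate_rng(rec.sequence, rng0))
           for rec in catalog]

    truth = [SyntheticTruth(peptide_id=rec.id, planted_log2fc=float(lfc[i]),
                            base_abundance=float(base[i]), is_null=lfc[i] == 0.0)
             for i, rec in enumerate(catalog)]

    samples: list[SampleReads] = []
    n_total = config.n_ctrl + config.n_case
    width = len(str(max(config.n_ctrl, config.n_case)))
    read_len = config.read_length_nt
    for s in range(n_total):
        is_ctrl = s < config.n_ctrl
        group = "control" if is_ctrl else "case"
        label = (f"ctrl{s + 1:0{width}d}" if is_ctrl
                 else f"case{s - config.n_ctrl + 1:0{width}d}")
        rng = np.random.default_rng([config.seed, 1 + s])
        mult = np.exp2(lfc / 2.0) if is_ctrl else np.exp2(-lfc / 2.0)
        jitter = rng.lognormal(0.0, config.sample_jitter_sigma, size=n_pep)
        frac = base * mult * jitter
        total = frac.sum()
        if total >= 1.0:
            raise ValueError(
                f"sample {label}: expected coding fraction {total:.3f} >= 1; "
                "lower abundance_log_mu or the catalog size")
        counts = rng.multinomial(config.reads_per_sample,
                                 np.append(frac, 1.0 - total))
        mat = rng.integers(0, 4, size=(config.reads_per_sample, read_len),
                           dtype=np.uint8)
        row = 0
        for p in range(n_pep):
            for _ in range(int(counts[p])):
                _coding_read(mat[row], cds[p], rng, read_len,
                             config.min_coding_overlap_nt)
                row += 1
        samples.append(SampleReads(sample_id=label, group=group, matrix=mat))
    return samples, truth


def simulate_null_abundance(n_peptides: int, n_ctrl: int, n_case: int,
                            seed: int, log_mu: float = math.log(200.0),
                            log_sigma: float = 1.0) -> AbundanceMatrix:
    """A global-null CPM matrix: both groups drawn from the same log-normal.

    Used to check false-discovery control of the funnel's FDR stage when no
    peptide is truly differential.
    """
    rng = np.random.default_rng([seed, 0])
    vals = rng.lognormal(log_mu, log_sigma, size=(n_peptides, n_ctrl + n_case))
    width = len(str(max(n_ctrl, n_case)))
    cols = ([f"ctrl{i + 1:0{width}d}" for i in range(n_ctrl)]
            + [f"case{i + 1:0{width}d}" for i in range(n_case)])
    groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=cols)
    df = pd.DataFrame(vals, index=[f"pep{i + 1}" for i in range(n_peptides)],
                      columns=cols)
    df.index.name = "peptide_id"
    return AbundanceMatrix(values=df, group_labels=groups)


def evaluate_recovery(retained_ids: Sequence[str],
                      truth: Sequence[SyntheticTruth]) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of a retained candidate set.

    The positives are the planted control-enriched peptides
    (``planted_log2fc > 0``); anything else retained counts as a false
    discovery.
    """
    retained = set(retained_ids)
    positives = {t.peptide_id for t in truth if t.planted_log2fc > 0}
    if not positives:
        raise ValueError("truth contains no planted control-enriched peptides")
    tp = len(retained & positives)
    return {
        "sensitivity": tp / len(positives),
        "fdp": (len(retained) - tp) / max(1, len(retained)),
        "n_positives": float(len(positives)),
        "n_retained": float(len(retained)),
    }


def write_cohort(samples: Sequence[SampleReads], truth: Sequence[SyntheticTruth],
                 catalog: PeptideCatalog, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write FASTQ per sample, a sample sheet, the truth table and the catalog.

    This is exactly the pipeline's file-input contract; returns the sample
    sheet as a DataFrame.
    """
    from .catalog_io import write_fasta

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for sample in samples:
        path = os.path.join(str(outdir), f"{sample.sample_id}.fastq")
        with open(path, "w") as fh:
            for i, seq in enumerate(sample.sequences()):
                fh.write(f"@{sample.sample_id}.{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
        rows.append({"sample_id": sample.sample_id, "group": sample.group,
                     "path": path})
    sheet = pd.DataFrame(rows)
    sheet.to_csv(os.path.join(str(outdir), "samples.tsv"), sep="\t", index=False)
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(
        os.path.join(str(outdir), "truth.tsv"), sep="\t", index=False)
    write_fasta(catalog, os.path.join(str(outdir), "catalog.fasta"))
    return sheet
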