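"""Per-peptide physicochemical descriptors and set-level contrasts.

Candidate peptides mined from metagenomes tend to differ from published
anticancer peptides in length, hydropathy and charge. This module computes
the descriptors used for that comparison — GRAVY (grand average of
hydropathy on the Kyte–Doolittle scale), a count-based net charge at neutral
pH, amino-acid composition and length histograms — and Welch t contrasts
between descriptor distributions of two peptide sets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy import stats

from ._genetic_code import CANONICAL_AA, CANONICAL_AA_SET
from .catalog_io import PeptideCatalog

__all__ = [
    "PhyschemProfile",
    "SetContrast",
    "gravy",
    "net_charge",
    "aa_composition",
    "length_bins",
    "contrast_sets",
    "profile_peptide",
    "profile_catalog",
]

#: residues counted positive / negative in the count-based net charge
_POSITIVE = ("K", "R")
_NEGATIVE = ("D", "E")


@dataclass(frozen=True)
class PhyschemProfile:
    peptide_id: str
    length: int
    gravy: float
    net_charge: int
    aa_freq: Mapping[str, float]


@dataclass(frozen=True)
class SetContrast:
    """Welch two-sample t contrast between two descriptor distributions."""

    statistic: float
    p_value: float
    direction: str  # "a higher" | "b higher" | "equal"
    test_name: str
    sidedness: str  # "two-sided" | "one-sided"
    degenerate: bool = False


def _check_canonical(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(sequence):
        if aa not in CANONICAL_AA_SET:
            raise ValueError(f"non-canonical residue {aa!r} at position {pos}")


def gravy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy over the sequence."""
    _check_canonical(sequence)
    return float(ProteinAnalysis(sequence).gravy())


def net_charge(sequence: str) -> int:
    """Count-based net charge at neutral pH: (#K + #R) − (#D + #E).

    Histidine and the termini are excluded; this is a deterministic
    integer-valued proxy, not a pKa titration.
    """
    _check_canonical(sequence)
    pos = sum(sequence.count(a) for a in _POSITIVE)
    neg = sum(sequence.count(a) for a in _NEGATIVE)
    return pos - neg


def aa_composition(sequence: str) -> dict[str, float]:
    """Fraction of each of the 20 canonical residues (zeros included)."""
    _check_canonical(sequence)
    n = len(sequence)
    return {aa: sequence.count(aa) / n for aa in CANONICAL_AA}


def length_bins(catalog: PeptideCatalog,
                bin_edges: Sequence[tuple[int, int]]) -> dict[str, int]:
    """Histogram of peptide lengths over closed [lo, hi] integer bins.

    Lengths falling outside every bin are counted under ``"overflow"``.
    Counts always sum to the catalog size.
    """
    for (lo, hi) in bin_edges:
        if lo > hi:
            raise ValueError(f"bin [{lo}, {hi}] is empty")
    flat = [e for pair in bin_edges for e in pair]
    if flat != sorted(flat) or len(set(flat)) != len(flat):
        raise ValueError("bin edges must be strictly increasing and non-overlapping")
    counts = {f"{lo}-{hi}": 0 for lo, hi in bin_edges}
    counts["overflow"] = 0
    for rec in catalog:
        n = len(rec.sequence)
        for lo, hi in bin_edges:
            if lo <= n <= hi:
                counts[f"{lo}-{hi}"] += 1
                break
        else:
            counts["overflow"] += 1
    return counts


def contrast_sets(values_a: Iterable[float], values_b: Iterable[float],
                  sidedness: str = "two-sided") -> SetContrast:
    """Welch (unequal-variance) t contrast between two value sets.

    ``sidedness="one-sided"`` tests the alternative in the direction of the
    observed mean difference (the reported p is then the one-sided p for
    that direction). Two identical constant sets are degenerate: the t
    statistic is undefined and p is set to 1 by convention.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least 2 values")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a > mean_b:
        direction = "a higher"
    elif mean_b > mean_a:
        direction = "b higher"
    else:
        direction = "equal"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and mean_a == mean_b:
        return SetContrast(statistic=0.0, p_value=1.0, direction="equal",
                           test_name="welch-t", sidedness=sidedness,
                           degenerate=True)
    if sidedness == "two-sided":
        alternative = "two-sided"
    else:
        alternative = "greater" if mean_a >= mean_b else "less"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return SetContrast(statistic=float(res.statistic), p_value=float(res.pvalue),
                       direction=direction, test_name="welch-t",
                       sidedness=sidedness)


def profile_peptide(peptide_id: str, sequence: str) -> PhyschemProfile:
    """All descriptors of one peptide."""
    return PhyschemProfile(peptide_id=peptide_id, length=len(sequence),
                           gravy=gravy(sequence), net_charge=net_charge(sequence),
                           aa_freq=aa_composition(sequence))


def profile_catalog(catalog: PeptideCatalog) -> pd.DataFrame:
    """Per-peptide profile table: id, length, gravy, net_charge, 20 fractions."""
    rows = []
    for rec in catalog:
        prof = profile_peptide(rec.id, rec.sequence)
        row = {"peptide_id": prof.peptide_id, "length": prof.length,
               "gravy": prof.gravy, "net_charge": prof.net_charge}
        row.update({f"freq_{aa}": prof.aa_freq[aa] for aa in CANONICAL_AA})
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(catalog: PeptideCatalog, path: str | os.PathLike) -> None:
    profile_catalog(catalog).to_csv(path, sep="\t", index=False)
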