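"""Global pairwise alignment and identity distributions.

Novelty of mined candidate peptides is assessed by optimal global alignment
(Needleman–Wunsch with affine gap penalties, Gotoh's three-state recurrence)
against reference anticancer-peptide sets, reporting percent identity as
identical columns over the full alignment length (gap columns included, end
gaps penalized). Defaults follow the EMBOSS ``needle`` conventions:
BLOSUM62, gap open 10, gap extend 0.5, with a gap of length L costing
``open + (L-1)*extend``.

Scores are computed in exact half-unit integer arithmetic (everything
doubled internally) so half-integer gap extends never produce float ties;
traceback is deterministic with state preference diagonal > up > left.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._genetic_code import blosum62, encode_protein
from .catalog_io import PeptideCatalog
from .physchem import SetContrast, contrast_sets

__all__ = [
    "AlignmentResult",
    "IdentityDistribution",
    "needleman_wunsch",
    "identity_distribution",
    "compare_identity_distributions",
]

_NEG = -(10 ** 9)  # effectively -inf in doubled-integer score units


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    alignment_length: int
    n_identical: int
    identity_pct: float


@dataclass(frozen=True)
class IdentityDistribution:
    """Pairwise identity percentages with a 10-point-bin histogram."""

    pair_identities: list[float]
    bin_counts: dict[str, int]
    fraction_over: dict[float, float]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame({
            "id_a": [p[0] for p in self.pairs],
            "id_b": [p[1] for p in self.pairs],
            "identity_pct": self.pair_identities,
        }).to_csv(path, sep="\t", index=False)


def needleman_wunsch(seq_a: str, seq_b: str,
                     matrix: Optional[np.ndarray] = None,
                     gap_open: float = 10.0,
                     gap_extend: float = 0.5) -> AlignmentResult:
    """Optimal global alignment of two peptides under affine gap penalties.

    ``matrix`` is a 20x20 substitution matrix in canonical residue order
    (BLOSUM62 by default). Penalties are positive; ``gap_open`` is charged
    for the first residue of a gap and ``gap_extend`` for each subsequent
    one. End gaps are penalized like internal ones.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if not gap_open >= gap_extend > 0:
        raise ValueError("need gap_open >= gap_extend > 0")
    sub2 = 2 * (blosum62() if matrix is None else np.asarray(matrix, dtype=np.int64))
    open2 = int(round(2 * gap_open))
    ext2 = int(round(2 * gap_extend))
    if abs(2 * gap_open - open2) > 1e-9 or abs(2 * gap_extend - ext2) > 1e-9:
        raise ValueError("gap penalties must be multiples of 0.5")
    a = encode_protein(seq_a)
    b = encode_protein(seq_b)
    n, m = len(a), len(b)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)   # ends in substitution
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # ends with gap in b ("up")
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # ends with gap in a ("left")
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -(open2 + (i - 1) * ext2)
    for j in range(1, m + 1):
        Iy[0, j] = -(open2 + (j - 1) * ext2)
    for i in range(1, n + 1):
        srow = sub2[a[i - 1]]
        for j in range(1, m + 1):
            s = srow[b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open2, Ix[i - 1, j] - ext2,
                           Iy[i - 1, j] - open2)
            Iy[i, j] = max(M[i, j - 1] - open2, Iy[i, j - 1] - ext2,
                           Ix[i, j - 1] - open2)

    # deterministic traceback: state preference diagonal > up > left
    tabs = {"M": M, "Ix": Ix, "Iy": Iy}
    i, j = n, m
    state = max(("M", "Ix", "Iy"), key=lambda s: (tabs[s][i, j], s == "M", s == "Ix"))
    score2 = int(tabs[state][i, j])
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = sub2[a[i - 1], b[j - 1]]
            prev = M[i, j] - s
            cols_a.append(seq_a[i - 1])
            cols_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            cur = Ix[i, j]
            cols_a.append(seq_a[i - 1])
            cols_b.append("-")
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - open2 == cur:
                state = "M"
            elif Ix[i, j] - ext2 == cur:
                state = "Ix"
            else:
                state = "Iy"
        else:
            cur = Iy[i, j]
            cols_a.append("-")
            cols_b.append(seq_b[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - open2 == cur:
                state = "M"
            elif Iy[i, j] - ext2 == cur:
                state = "Iy"
            else:
                state = "Ix"
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    length = len(aligned_a)
    n_ident = sum(x == y for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(
        score=score2 / 2.0,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        alignment_length=length,
        n_identical=n_ident,
        identity_pct=100.0 * n_ident / length,
    )


def identity_distribution(set_a: PeptideCatalog,
                          set_b: Optional[PeptideCatalog] = None,
                          within: bool = False,
                          thresholds: Sequence[float] = (80.0,),
                          gap_open: float = 10.0,
                          gap_extend: float = 0.5) -> IdentityDistribution:
    """Pairwise identity distribution within one set or across two sets.

    With ``within=True`` all unordered pairs inside ``set_a`` are aligned
    (self-pairs excluded); otherwise all cross pairs ``set_a x set_b``.
    The histogram uses ten-point bins, the last bin closed at 100.
    """
    if within:
        if len(set_a) < 2:
            raise ValueError("within-set distribution needs at least 2 peptides")
        pairs = list(itertools.combinations(set_a.records, 2))
    else:
        if set_b is None or len(set_a) == 0 or len(set_b) == 0:
            raise ValueError("cross-set distribution needs two non-empty sets")
        pairs = list(itertools.product(set_a.records, set_b.records))
    idents: list[float] = []
    ids: list[tuple[str, str]] = []
    for ra, rb in pairs:
        res = needleman_wunsch(ra.sequence, rb.sequence,
                               gap_open=gap_open, gap_extend=gap_extend)
        idents.append(res.identity_pct)
        ids.append((ra.id, rb.id))
    edges = np.arange(0, 101, 10)
    counts, _ = np.histogram(idents, bins=edges)
    bin_counts = {f"{edges[k]}-{edges[k + 1]}": int(counts[k])
                  for k in range(len(counts))}
    frac = {float(t): float(np.mean([x > t for x in idents])) for t in thresholds}
    return IdentityDistribution(pair_identities=idents, bin_counts=bin_counts,
                                fraction_over=frac, pairs=ids)


def compare_identity_distributions(dist_a: IdentityDistribution,
                                   dist_b: IdentityDistribution) -> SetContrast:
    """One-sided Welch t contrast between two identity distributions."""
    if len(dist_a.pair_identities) < 2 or len(dist_b.pair_identities) < 2:
        raise ValueError("each distribution needs at least 2 pairs")
    return contrast_sets(dist_a.pair_identities, dist_b.pair_identities,
                         sidedness="one-sided")
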