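"""Shared alphabet and genetic-code tables.

Integer encodings used across the mapper and the simulator:

* nucleotides ``A C G T N`` -> ``0..4``
* amino acids in :data:`CANONICAL_AA` order -> ``0..19``
* ``20`` encodes a translation stop, ``21`` the unknown residue ``X``
  (produced by any codon containing ``N``)

The codon table itself comes from the standard genetic code (NCBI table 1)
as shipped with Biopython; BLOSUM62 likewise.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
CANONICAL_AA_SET = frozenset(CANONICAL_AA)

STOP_CODE = 20
X_CODE = 21

NT_ORDER = "ACGTN"
NT_INDEX = {nt: i for i, nt in enumerate(NT_ORDER)}
# complement under the 0..4 encoding (N is its own complement)
NT_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_std_table = CodonTable.unambiguous_dna_by_id[1]

#: codon string -> one-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_std_table.forward_table)
for _stop in _std_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> tuple of synonymous codons (sorted, for reproducible choice)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_std_table.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)


@functools.cache
def codon_code_table() -> np.ndarray:
    """Return the 125-entry codon translation table.

    Index is ``25*b0 + 5*b1 + b2`` over the 0..4 nucleotide codes; the value
    is the amino-acid code, :data:`STOP_CODE`, or :data:`X_CODE` for any
    codon containing ``N``.
    """
    table = np.full(125, X_CODE, dtype=np.uint8)
    for codon, aa in CODON_TO_AA.items():
        idx = 25 * NT_INDEX[codon[0]] + 5 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]
        table[idx] = STOP_CODE if aa == "*" else AA_INDEX[aa]
    return table


@functools.cache
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 20x20 int array in :data:`CANONICAL_AA` order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(CANONICAL_AA):
        for j, b in enumerate(CANONICAL_AA):
            out[i, j] = int(mat[a, b])
    return out


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string over ``ACGTN`` (case-insensitive) as uint8 codes."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for nt, code in NT_INDEX.items():
        out[arr == ord(nt)] = code
    if (out == 255).any():
        pos = int(np.argmax(out == 255))
        raise ValueError(f"non-ACGTN base {seq[pos]!r} at position {pos}")
    return out


def decode_dna(codes: np.ndarray) -> str:
    return "".join(NT_ORDER[c] for c in codes)


def encode_protein(seq: str) -> np.ndarray:
    """Encode a canonical amino-acid string as uint8 codes 0..19."""
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.uint8)
    except KeyError as exc:
        bad = exc.args[0]
        raise ValueError(
            f"non-canonical residue {bad!r} at position {seq.index(bad)}"
        ) from None


def decode_protein(codes: np.ndarray) -> str:
    return "".join(CANONICAL_AA[c] for c in codes)


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return NT_COMPLEMENT[codes[::-1]]
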