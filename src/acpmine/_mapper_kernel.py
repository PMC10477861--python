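"""Compiled batch kernel for the protein-space read mapper.

Implements exactly the semantics of :func:`acpmine.abundance.map_read`
(six-frame translation, k-mer seeding, ungapped best-valid-span scoring,
lexicographic tie-break) over whole read matrices at once.

Speed trick: a candidate diagonal is only span-scored when it collected at
least two seed hits, whenever that filter is provably lossless for the
active thresholds — any span of length L with at most
``L - ceil(min_identity*L)`` mismatches contains an exact run of at least
``ceil((L - m)/(m + 1))`` residues, and if that bound is ``>= k+1`` for
every feasible L the run carries two overlapping k-mers on the same
diagonal. For the defaults (k=4, min_match_len=8, min_identity=0.9) the
bound is 5, so the filter is exact; otherwise the kernel falls back to
scoring single-seed diagonals too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._genetic_code import blosum62, codon_code_table, encode_protein
from .catalog_io import PeptideCatalog

_DIAG_SHIFT = 4096       # diag offset inside packed (pep, diag) keys
_DIAG_SPAN = 8192        # keys are pep * _DIAG_SPAN + diag + _DIAG_SHIFT
_MAX_PEP_LEN = _DIAG_SHIFT - 1


@dataclass
class PackedCatalog:
    """Catalog flattened into arrays for the kernel, plus a k-mer table."""

    kmer_size: int
    n_peptides: int
    pep_seq: np.ndarray      # concatenated residue codes
    pep_start: np.ndarray    # n+1 offsets into pep_seq
    pep_len: np.ndarray
    lex_rank: np.ndarray     # lexicographic rank of each peptide id
    kmer_start: np.ndarray   # 20**k + 1 prefix offsets into postings
    post_pep: np.ndarray
    post_off: np.ndarray
    max_pep_len: int

    @classmethod
    def from_catalog(cls, catalog: PeptideCatalog, kmer_size: int) -> "PackedCatalog":
        if not 3 <= kmer_size <= 5:
            raise ValueError("batch kernel supports kmer_size in [3, 5]")
        seqs = [encode_protein(r.sequence) for r in catalog]
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        if lens.max(initial=0) > _MAX_PEP_LEN:
            raise ValueError(f"peptides longer than {_MAX_PEP_LEN} residues unsupported")
        start = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum(lens, out=start[1:])
        flat = (np.concatenate(seqs) if seqs else np.empty(0, dtype=np.uint8))
        ids = catalog.ids
        order = sorted(range(len(ids)), key=lambda i: ids[i])
        rank = np.empty(len(ids), dtype=np.int64)
        for r, i in enumerate(order):
            rank[i] = r
        codes, peps, offs = [], [], []
        for p, s in enumerate(seqs):
            if len(s) < kmer_size:
                continue
            s64 = s.astype(np.int64)
            c = np.zeros(len(s) - kmer_size + 1, dtype=np.int64)
            for x in range(kmer_size):
                c = c * 20 + s64[x:len(s) - kmer_size + 1 + x]
            codes.append(c)
            peps.append(np.full(len(c), p, dtype=np.int64))
            offs.append(np.arange(len(c), dtype=np.int64))
        if codes:
            code_all = np.concatenate(codes)
            pep_all = np.concatenate(peps)
            off_all = np.concatenate(offs)
            srt = np.argsort(code_all, kind="stable")
            code_all, pep_all, off_all = code_all[srt], pep_all[srt], off_all[srt]
        else:
            code_all = np.empty(0, dtype=np.int64)
            pep_all = np.empty(0, dtype=np.int64)
            off_all = np.empty(0, dtype=np.int64)
        n_codes = 20 ** kmer_size
        kmer_start = np.zeros(n_codes + 1, dtype=np.int64)
        np.cumsum(np.bincount(code_all, minlength=n_codes), out=kmer_start[1:])
        return cls(kmer_size=kmer_size, n_peptides=len(ids), pep_seq=flat,
                   pep_start=start, pep_len=lens, lex_rank=rank,
                   kmer_start=kmer_start, post_pep=pep_all, post_off=off_all,
                   max_pep_len=int(lens.max(initial=0)))


def _two_seed_exact(kmer_size: int, min_match_len: int, min_identity: float,
                    max_pep_len: int, max_frag_len: int) -> bool:
    """True when every valid span must seed >= 2 k-mers on its diagonal."""
    for span in range(min_match_len, min(max_pep_len, max_frag_len) + 1):
        mism = span - math.ceil(min_identity * span - 1e-9)
        min_run = math.ceil((span - mism) / (mism + 1))
        if min_run < kmer_size + 1:
            return False
    return True


@njit(cache=True)
def _kernel(reads, lens, codon_tab, pep_seq, pep_start, pep_len, lex_rank,
            kmer_start, post_pep, post_off, k, min_orf, min_match,
            min_ident, sub, require_two):  # pragma: no cover - exercised via wrapper
    n_reads = reads.shape[0]
    out = np.full(n_reads, -1, dtype=np.int64)
    max_len = reads.shape[1]
    rc = np.empty(max_len, dtype=np.uint8)
    aa = np.empty(max_len // 3 + 1, dtype=np.int64)
    keys = np.empty(1 << 16, dtype=np.int64)
    kpow = 20 ** (k - 1)
    maxpep = pep_len.max() if pep_len.size else 0
    pm = np.empty(maxpep + max_len + 2, dtype=np.int64)
    ps = np.empty(maxpep + max_len + 2, dtype=np.int64)

    for r in range(n_reads):
        L = lens[r]
        best_score = np.int64(-(1 << 60))
        best_rank = np.int64(1 << 60)
        best_pep = np.int64(-1)
        found = False
        for c in range(L):
            base = reads[r, L - 1 - c]
            rc[c] = 4 if base == 4 else 3 - base
        for strand in range(2):
            for frame in range(3):
                n_codons = (L - frame) // 3
                if n_codons <= 0:
                    continue
                for t in range(n_codons):
                    i = frame + 3 * t
                    if strand == 0:
                        b0, b1, b2 = reads[r, i], reads[r, i + 1], reads[r, i + 2]
                    else:
                        b0, b1, b2 = rc[i], rc[i + 1], rc[i + 2]
                    aa[t] = codon_tab[25 * b0 + 5 * b1 + b2]
                # scan fragments (runs of residues < 20)
                start = 0
                for t in range(n_codons + 1):
                    if t < n_codons and aa[t] < 20:
                        continue
                    flen = t - start
                    if flen >= min_orf and flen >= k:
                        # collect seed keys
                        ncand = 0
                        overflow = False
                        code = np.int64(0)
                        for i in range(flen):
                            code = (code % kpow) * 20 + aa[start + i]
                            if i < k - 1:
                                continue
                            w = i - k + 1
                            p0 = kmer_start[code]
                            p1 = kmer_start[code + 1]
                            for pp in range(p0, p1):
                                key = post_pep[pp] * _DIAG_SPAN + (w - post_off[pp]) + _DIAG_SHIFT
                                if ncand < keys.shape[0]:
                                    keys[ncand] = key
                                    ncand += 1
                                else:
                                    overflow = True
                        if ncand == 0:
                            start = t + 1
                            continue
                        cand = np.sort(keys[:ncand])
                        need_two = require_two and not overflow
                        q = 0
                        while q < ncand:
                            q2 = q
                            while q2 < ncand and cand[q2] == cand[q]:
                                q2 += 1
                            if (not need_two) or (q2 - q >= 2):
                                key = cand[q]
                                pep = key // _DIAG_SPAN
                                diag = key % _DIAG_SPAN - _DIAG_SHIFT
                                plen = pep_len[pep]
                                i0 = diag if diag > 0 else 0
                                j0 = -diag if diag < 0 else 0
                                lo = min(flen - i0, plen - j0)
                                if lo >= min_match:
                                    pbase = pep_start[pep]
                                    pm[0] = 0
                                    ps[0] = 0
                                    for x in range(lo):
                                        fa = aa[start + i0 + x]
                                        pa = pep_seq[pbase + j0 + x]
                                        pm[x + 1] = pm[x] + (1 if fa == pa else 0)
                                        ps[x + 1] = ps[x] + sub[fa, pa]
                                    for st in range(lo - min_match + 1):
                                        for en in range(st + min_match, lo + 1):
                                            span = en - st
                                            if pm[en] - pm[st] >= min_ident * span - 1e-9:
                                                sc = ps[en] - ps[st]
                                                if (not found) or sc > best_score or (
                                                        sc == best_score and lex_rank[pep] < best_rank):
                                                    best_score = sc
                                                    best_rank = lex_rank[pep]
                                                    best_pep = pep
                                                    found = True
                            q = q2
                    start = t + 1
        if found:
            out[r] = best_pep
    return out


def map_reads_batch(reads: np.ndarray, lens: np.ndarray, packed: PackedCatalog,
                    params) -> np.ndarray:
    """Map a padded uint8 read matrix; returns peptide indices (-1 = no hit)."""
    if packed.kmer_size != params.kmer_size:
        raise ValueError("packed catalog built with a different kmer_size")
    max_frag = reads.shape[1] // 3 + 1
    require_two = _two_seed_exact(params.kmer_size, params.min_match_len,
                                  params.min_identity, packed.max_pep_len, max_frag)
    return _kernel(
        np.ascontiguousarray(reads, dtype=np.uint8),
        np.asarray(lens, dtype=np.int64),
        codon_code_table(), packed.pep_seq.astype(np.uint8), packed.pep_start,
        packed.pep_len, packed.lex_rank, packed.kmer_start, packed.post_pep,
        packed.post_off, params.kmer_size, params.min_orf_len,
        params.min_match_len, float(params.min_identity), blosum62(),
        require_two,
    )
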