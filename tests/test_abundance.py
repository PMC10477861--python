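"""Protein-space mapping and CPM profiling against brute-force oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from acpmine import (
    MappingParams,
    SampleReads,
    build_kmer_index,
    generate_catalog,
    map_read,
    profile_abundance,
    reverse_translate,
    translate_six_frames,
)
from acpmine._genetic_code import CANONICAL_AA, blosum62
from acpmine._mapper_kernel import PackedCatalog, map_reads_batch
from conftest import make_catalog

_AAI = {a: i for i, a in enumerate(CANONICAL_AA)}
_BLOSUM = blosum62()


def biopython_six_frames(read, min_orf_len):
    """Independent six-frame fragmentation via Biopython translation."""
    frags = []
    seqs = [Seq(read), Seq(read).reverse_complement()]
    for s in seqs:
        for frame in range(3):
            n = (len(s) - frame) // 3
            if n <= 0:
                continue
            aa = str(s[frame:frame + 3 * n].translate())
            for piece in aa.replace("X", "*").split("*"):
                if len(piece) >= min_orf_len:
                    frags.append(piece)
    return frags


def brute_force_map(read, catalog, params):
    """All-vs-all ungapped alignment of every fragment at every offset."""
    best = None
    for frag in biopython_six_frames(read, params.min_orf_len):
        f = np.array([_AAI[c] for c in frag])
        for rec in catalog:
            p = np.array([_AAI[c] for c in rec.sequence])
            for i in range(len(f)):
                for j in range(len(p)):
                    max_l = min(len(f) - i, len(p) - j)
                    for ell in range(params.min_match_len, max_l + 1):
                        fs, ps = f[i:i + ell], p[j:j + ell]
                        if (fs == ps).sum() >= params.min_identity * ell - 1e-9:
                            sc = int(_BLOSUM[fs, ps].sum())
                            cand = (sc, rec.id)
                            if (best is None or sc > best[0]
                                    or (sc == best[0] and rec.id < best[1])):
                                best = cand
    return None if best is None else best[1]


class TestTranslateSixFrames:
    def test_forward_frame_translation(self):
        assert "MAK" in translate_six_frames("ATGGCCAAA" * 3, min_orf_len=3)[0]

    def test_matches_biopython_on_random_reads(self, rng):
        for _ in range(50):
            read = "".join(rng.choice(list("ACGT"), rng.integers(10, 80)))
            assert sorted(translate_six_frames(read, 5)) == sorted(
                biopython_six_frames(read, 5))

    def test_n_codons_produce_x_and_split(self):
        # ATG GCC NAA AAA GCT ... the N codon splits the frame-1 fragment
        read = "ATGGCCNAAAAAGCTTTTGGGCAC"
        frags = translate_six_frames(read, min_orf_len=2)
        assert "MA" in frags
        assert not any("X" in f for f in frags)

    def test_reverse_complement_mirrors_frames(self, rng):
        read = "".join(rng.choice(list("ACGT"), 60))
        rc = str(Seq(read).reverse_complement())
        assert sorted(translate_six_frames(read, 6)) == sorted(
            translate_six_frames(rc, 6))

    def test_in_frame_stop_splits(self):
        read = "ATGGCCAAATAAATGGCCAAA"  # MAK * MAK in frame +1
        frags = translate_six_frames(read, min_orf_len=3)
        assert frags.count("MAK") == 2

    def test_short_read_gives_empty_list(self):
        assert translate_six_frames("ATGGCC", min_orf_len=8) == []


class TestKmerIndex:
    def test_small_catalog_keys(self):
        idx = build_kmer_index(make_catalog(["MKTP"]), 3)
        assert set(idx.postings) == {"MKT", "KTP"}
        assert idx.postings["MKT"] == [("p1", 0)]

    def test_shared_kmer_two_postings(self):
        idx = build_kmer_index(make_catalog(["AMKTA", "CMKTC"]), 3)
        assert len(idx.postings["MKT"]) == 2

    def test_short_peptides_excluded(self):
        idx = build_kmer_index(make_catalog(["MK", "MKTP"]), 4)
        assert all(pid == "p2" for posts in idx.postings.values()
                   for pid, _ in posts)


class TestMapRead:
    def test_exact_substring_maps(self, random_catalog):
        idx = build_kmer_index(random_catalog, 4)
        rec = random_catalog.records[3]
        read = reverse_translate(rec.sequence[:10], seed=5)
        assert map_read(read, idx, random_catalog) == rec.id

    def test_random_read_no_hit(self, random_catalog, rng):
        idx = build_kmer_index(random_catalog, 4)
        read = "".join(rng.choice(list("ACGT"), 100))
        # uniform-random reads essentially never reach 90% identity over 8+
        assert map_read(read, idx, random_catalog) == brute_force_map(
            read, random_catalog, MappingParams())

    def test_tie_breaks_to_smaller_id(self):
        shared = "MKTAYWQRVL"
        cat = make_catalog([shared + "AAAA", shared + "CCCC"], prefix="z")
        # rename to make lexicographic order differ from catalog order
        from acpmine import PeptideCatalog, PeptideRecord
        cat = PeptideCatalog(records=[
            PeptideRecord(id="b_pep", sequence=shared + "AAAA"),
            PeptideRecord(id="a_pep", sequence=shared + "CCCC"),
        ])
        idx = build_kmer_index(cat, 4)
        read = reverse_translate(shared, seed=1)
        assert map_read(read, idx, cat) == "a_pep"

    def test_agrees_with_brute_force_oracle(self, rng):
        catalog = generate_catalog(10, (9, 18), seed=77)
        idx = build_kmer_index(catalog, 4)
        params = MappingParams()
        n_hits = 0
        for trial in range(60):
            if trial % 3 == 0:
                read = "".join(rng.choice(list("ACGT"), rng.integers(24, 61)))
            else:
                rec = catalog.records[rng.integers(0, len(catalog))]
                start = rng.integers(0, max(1, len(rec.sequence) - 9))
                read = reverse_translate(rec.sequence[start:start + 10],
                                         seed=int(rng.integers(1 << 30)))
                if trial % 3 == 2:  # mutate one base
                    pos = int(rng.integers(0, len(read)))
                    read = read[:pos] + "ACGT"[int(rng.integers(4))] + read[pos + 1:]
            expected = brute_force_map(read, catalog, params)
            assert map_read(read, idx, catalog, params) == expected
            n_hits += expected is not None
        assert n_hits > 10  # the oracle exercise includes real hits


class TestBatchKernel:
    def test_agrees_with_reference_mapper(self, rng):
        catalog = generate_catalog(25, (10, 40), seed=3)
        idx = build_kmer_index(catalog, 4)
        params = MappingParams()
        reads = []
        for trial in range(120):
            if trial % 2:
                reads.append("".join(rng.choice(list("ACGT"), 100)))
            else:
                rec = catalog.records[rng.integers(0, len(catalog))]
                cds = reverse_translate(rec.sequence, seed=int(rng.integers(1 << 30)))
                pad = "".join(rng.choice(list("ACGT"), 100))
                read = (pad[:40] + cds + pad[40:])[:100]
                if trial % 4 == 0:
                    read = str(Seq(read).reverse_complement())
                reads.append(read)
        sample = SampleReads("s1", "control", reads=reads)
        mat, lens = sample.encoded()
        packed = PackedCatalog.from_catalog(catalog, 4)
        hits = map_reads_batch(mat, lens, packed, params)
        for read, hit in zip(reads, hits):
            ref = map_read(read, idx, catalog, params)
            got = None if hit < 0 else catalog.ids[hit]
            assert got == ref, read

    def test_handles_n_bases(self):
        catalog = generate_catalog(5, (12, 20), seed=9)
        reads = [reverse_translate(catalog.records[0].sequence, seed=1)]
        reads.append(reads[0][:10] + "N" * 5 + reads[0][15:])
        sample = SampleReads("s1", "case", reads=reads)
        mat, lens = sample.encoded()
        packed = PackedCatalog.from_catalog(catalog, 4)
        hits = map_reads_batch(mat, lens, packed, MappingParams())
        idx = build_kmer_index(catalog, 4)
        for read, hit in zip(reads, hits):
            got = None if hit < 0 else catalog.ids[hit]
            assert got == map_read(read, idx, catalog)


class TestProfileAbundance:
    def _single_peptide_sample(self, catalog, rec, n_reads, rng):
        cds = reverse_translate(rec.sequence, seed=11)
        reads = []
        for _ in range(n_reads):
            start = int(rng.integers(0, max(1, len(cds) - 60)))
            reads.append(cds[start:start + 60])
        return SampleReads("s1", "control", reads=reads)

    def test_cpm_definition(self):
        catalog = generate_catalog(3, (12, 20), seed=5)
        rng = np.random.default_rng(0)
        sample = self._single_peptide_sample(catalog, catalog.records[1], 50, rng)
        matrix = profile_abundance([sample], catalog, engine="python")
        col = matrix.values["s1"]
        # all reads derive from p2's coding sequence: CPM concentrates there
        assert col[catalog.ids[1]] == pytest.approx(50 * 1e6 / 50)
        assert (col.drop(catalog.ids[1]) == 0).all()

    def test_column_sums_bounded_and_order_invariant(self, rng):
        catalog = generate_catalog(6, (12, 20), seed=8)
        reads = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
        reads += [reverse_translate(catalog.records[2].sequence, seed=4)[:45]
                  for _ in range(10)]
        m1 = profile_abundance([SampleReads("a", "case", reads=reads)],
                               catalog, engine="python")
        m2 = profile_abundance([SampleReads("a", "case", reads=reads[::-1])],
                               catalog, engine="python")
        assert np.allclose(m1.values, m2.values)
        assert m1.values["a"].sum() <= 1e6

    def test_duplicating_reads_leaves_cpm_unchanged(self):
        catalog = generate_catalog(4, (12, 20), seed=2)
        reads = [reverse_translate(catalog.records[0].sequence, seed=s)[:36]
                 for s in range(8)]
        m1 = profile_abundance([SampleReads("a", "control", reads=reads)],
                               catalog, engine="python")
        m2 = profile_abundance([SampleReads("a", "control", reads=reads * 2)],
                               catalog, engine="python")
        assert np.allclose(m1.values, m2.values)

    def test_zero_read_sample_errors(self):
        catalog = generate_catalog(2, (12, 20), seed=1)
        sample = SampleReads("a", "control", reads=["ACGTACGT"])
        sample.total_reads = 0
        with pytest.raises(ValueError):
            profile_abundance([sample], catalog, engine="python")

    def test_tsv_round_trip(self, tmp_path):
        from acpmine import AbundanceMatrix

        catalog = generate_catalog(3, (12, 20), seed=5)
        reads = [reverse_translate(catalog.records[0].sequence, seed=3)[:45]]
        m = profile_abundance(
            [SampleReads("c1", "control", reads=reads),
             SampleReads("k1", "case", reads=reads)],
            catalog, engine="python")
        path = tmp_path / "abund.tsv"
        m.to_tsv(path)
        back = AbundanceMatrix.from_tsv(path)
        assert np.allclose(back.values, m.values)
        assert list(back.group_labels) == ["control", "case"]
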