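"""Sequence I/O, ORF calling, translation and identity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgrscan.genome_io import (
    GenomeRecord,
    OrfRecord,
    ParseError,
    find_orfs,
    orf_coding_sequence,
    pairwise_identity,
    read_fasta,
    read_genbank,
    revcomp,
    translate,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgt\n")
        (rec,) = read_fasta(p)
        assert (rec.id, rec.seq, rec.length) == ("x", "ACGT", 4)

    def test_two_records_order_preserved(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAAAA\n>b\nCCCC\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]

    def test_u_mapped_to_t(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">r\nacgu\n")
        assert read_fasta(p)[0].seq == "ACGT"

    def test_bad_alphabet_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">r\nACGJ\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">r\n>s\nACGT\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    def test_round_trip_byte_identical(self, tmp_path):
        recs = [
            GenomeRecord(id="g1", seq="ACGTN" * 30),
            GenomeRecord(id="g2", seq="TTTTGGGG"),
        ]
        p = tmp_path / "out.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


MINIMAL_GBK = """\
LOCUS       test6                9 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  minimal record.
ACCESSION   test6
FEATURES             Location/Qualifiers
     CDS             {location}
                     /product="demo protein"
ORIGIN
        1 atgaaataa
//
"""


class TestGenBank:
    def test_plus_strand_cds(self, tmp_path):
        p = tmp_path / "a.gbk"
        p.write_text(MINIMAL_GBK.format(location="1..6"))
        genome, orfs = read_genbank(p)
        assert genome.length == 9
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, 6, "+")
        assert orfs[0].label == "demo protein"

    def test_complement_cds(self, tmp_path):
        p = tmp_path / "a.gbk"
        p.write_text(MINIMAL_GBK.format(location="complement(4..9)"))
        _, orfs = read_genbank(p)
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (3, 9, "-")

    def test_missing_origin_is_error(self, tmp_path):
        p = tmp_path / "a.gbk"
        p.write_text(
            "LOCUS       x  9 bp DNA linear PHG 01-JAN-2024\n"
            "FEATURES             Location/Qualifiers\n//\n"
        )
        with pytest.raises(ParseError):
            read_genbank(p)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAC", "N"), ("AATAAC", "NN"), ("TACTGC", "YC"), ("TAA", "*")],
    )
    def test_codon_table(self, seq, expected):
        assert translate(seq) == expected

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError):
            translate("ACGT")


def _orfs_bruteforce(seq: str, min_aa: int):
    """Independent 6-frame scan: regex-free codon walk per frame/strand."""
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            start_idx = None
            for ci, codon in enumerate(codons):
                if codon in ("TAA", "TAG", "TGA"):
                    if start_idx is not None and ci - start_idx >= min_aa:
                        a = frame + 3 * start_idx
                        b = frame + 3 * (ci + 1)
                        if strand == "-":
                            a, b = L - b, L - a
                        found.add((a, b, strand))
                    start_idx = None
                elif start_idx is None and codon in ("ATG", "GTG", "TTG"):
                    start_idx = ci
    return found


class TestFindOrfs:
    def test_simple_orf(self):
        g = GenomeRecord(id="g", seq="ATGAAATAA")
        (orf,) = find_orfs(g, min_aa=2)
        assert (orf.start, orf.end, orf.strand, orf.protein) == (0, 9, "+", "MK")

    def test_strand_symmetry(self):
        g = GenomeRecord(id="g", seq=revcomp("ATGAAATAA"))
        (orf,) = find_orfs(g, min_aa=2)
        assert (orf.start, orf.end, orf.strand, orf.protein) == (0, 9, "-", "MK")

    def test_matches_bruteforce_on_random_genomes(self):
        import numpy as np

        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            g = GenomeRecord(id="g", seq=seq)
            got = {(o.start, o.end, o.strand) for o in find_orfs(g, min_aa=10)}
            assert got == _orfs_bruteforce(seq, 10)

    def test_coordinates_translate_back(self):
        import numpy as np

        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        g = GenomeRecord(id="g", seq=seq)
        for orf in find_orfs(g, min_aa=15):
            assert translate(orf_coding_sequence(g, orf)) == orf.protein + "*"
            assert "*" not in orf.protein


def _gotoh_bounds(a, b, match=1.0, mismatch=-1.0, open_=-10.0, extend=-0.5):
    """Quadratic-space affine-gap DP; returns (score, min_ident, max_ident).

    Tracks, per cell and gap state, the best score together with the
    smallest and largest identity count among co-optimal alignments, so the
    production identity must land inside [min_ident, max_ident].
    """
    NEG = float("-inf")
    n, m = len(a), len(b)

    def better(cur, cand):
        return cand if cand[0] > cur[0] + 1e-9 else cur

    # state: (score, min_id, max_id) for M (diag), X (gap in b), Y (gap in a)
    def merge(*cands):
        best = max(c[0] for c in cands)
        lo = min(c[1] for c in cands if c[0] > best - 1e-9)
        hi = max(c[2] for c in cands if c[0] > best - 1e-9)
        return (best, lo, hi)

    M = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0, 0)
    for i in range(1, n + 1):
        X[i][0] = (open_ + (i - 1) * extend, 0, 0)
    for j in range(1, m + 1):
        Y[0][j] = (open_ + (j - 1) * extend, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            inc = 1 if a[i - 1] == b[j - 1] else 0
            prev = merge(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (prev[0] + s, prev[1] + inc, prev[2] + inc)
            xo = merge(M[i - 1][j], Y[i - 1][j])
            X[i][j] = merge(
                (xo[0] + open_, xo[1], xo[2]),
                (X[i - 1][j][0] + extend, X[i - 1][j][1], X[i - 1][j][2]),
            )
            yo = merge(M[i][j - 1], X[i][j - 1])
            Y[i][j] = merge(
                (yo[0] + open_, yo[1], yo[2]),
                (Y[i][j - 1][0] + extend, Y[i][j - 1][1], Y[i][j - 1][2]),
            )
    return merge(M[n][m], X[n][m], Y[n][m])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @given(dna, dna)
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_identity_within_cooptimal_bounds_of_reference_dp(self):
        import numpy as np

        rng = np.random.default_rng(42)
        for _ in range(25):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            score, lo, hi = _gotoh_bounds(a, b)
            ident = pairwise_identity(a, b)
            # alignment length >= 60; identity from an optimal alignment
            assert lo / 120 <= ident <= hi / 60 + 1e-12

    def test_protein_mode_uses_blosum(self):
        # one conservative substitution out of ten residues
        assert pairwise_identity("MKVLWAALLV", "MKVLWAGLLV", mode="protein") == 0.9
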