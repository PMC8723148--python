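import numpy as np
import pytest

from svtab.datamodel import Breakend, SVRecord, SVTabError, build_container
from svtab.microhomology import ReferenceGenome, homology_at_junction, infer_microhomology

from conftest import make_del

_RC = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def oracle_homology(seqs: dict, bp1, bp2, max_len: int):
    """Direct enumeration of the two-way extension definition.

    Independent of the implementation: plain 1-based slicing with explicit
    reverse-complementation of non-canonical-strand flanks, trying every
    extension length.
    """

    def get(chrom, a, b):
        s = seqs[chrom].upper()
        a, b = max(a, 1), min(b, len(s))
        return s[a - 1:b] if a <= b else ""

    def flanks(bp, canonical):
        if bp.strand == canonical:
            return (
                lambda h: get(bp.chrom, bp.pos + 1, bp.pos + h),
                lambda h: get(bp.chrom, bp.pos - h + 1, bp.pos),
            )
        return (
            lambda h: _rc(get(bp.chrom, bp.pos - h + 1, bp.pos)),
            lambda h: _rc(get(bp.chrom, bp.pos + 1, bp.pos + h)),
        )

    fwd1, bwd1 = flanks(bp1, "+")
    fwd2, bwd2 = flanks(bp2, "-")

    def longest(fa, fb, limit):
        best = 0
        for h in range(1, limit + 1):
            x, y = fa(h), fb(h)
            if len(x) == h and len(y) == h and x == y and "N" not in x:
                best = h
        return best

    f = longest(fwd1, fwd2, max_len)
    b = longest(bwd1, bwd2, max_len - f)
    cap = max_len
    if bp1.chrom == bp2.chrom:
        cap = min(cap, abs(bp2.pos - bp1.pos))
    f = min(f, cap)
    b = min(b, cap - f)
    if bp1.strand == "+":
        seq = get(bp1.chrom, bp1.pos - b + 1, bp1.pos + f)
    else:
        seq = _rc(get(bp1.chrom, bp1.pos - f + 1, bp1.pos + b))
    return f + b, seq


class TestWorkedExamples:
    def test_deletion_with_two_way_homology(self):
        # forward TAG/TAG (3), backward C/C (1) around the junction
        ref = {"chr1": "AGCTAGTCTAGG"}
        out = homology_at_junction(ref, Breakend("chr1", 3, "+"), Breakend("chr1", 8, "-"), 10)
        assert out == (4, "CTAG")

    def test_no_shared_bases_gives_zero(self):
        ref = {"chr1": "AAAACCCCGGGGTTTT"}
        out = homology_at_junction(ref, Breakend("chr1", 4, "+"), Breakend("chr1", 12, "-"), 3)
        assert out == (0, "")

    def test_tandem_repeat_capped_at_svlen(self):
        # one 4-bp unit of a perfect repeat: homology extends past the
        # deleted unit but cannot exceed its length
        ref = {"chr1": "ACGTACGTACGT"}
        hom_len, hom_seq = homology_at_junction(
            ref, Breakend("chr1", 4, "+"), Breakend("chr1", 8, "-"), 200
        )
        assert hom_len == 4
        assert len(hom_seq) == 4

    def test_max_len_zero(self):
        ref = {"chr1": "ACGTACGTACGT"}
        assert homology_at_junction(ref, Breakend("chr1", 4, "+"), Breakend("chr1", 8, "-"), 0) == (0, "")

    def test_missing_contig(self):
        with pytest.raises(SVTabError, match="chrX"):
            homology_at_junction({"chr1": "ACGT"}, Breakend("chrX", 1, "+"), Breakend("chr1", 2, "-"), 5)


class TestOracleEquivalence:
    def test_random_junctions_match_enumeration(self, toy_reference):
        seqs = {"chr1": toy_reference.fetch("chr1", 1, toy_reference.length("chr1"))}
        rng = np.random.default_rng(13)
        strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
        for _ in range(1000):
            p1, p2 = sorted(int(x) for x in rng.integers(2, 9_999, size=2))
            if p1 == p2:
                continue
            s1, s2 = strands[rng.integers(0, 4)]
            max_len = int(rng.integers(0, 40))
            bp1, bp2 = Breakend("chr1", p1, s1), Breakend("chr1", p2, s2)
            got = homology_at_junction(toy_reference, bp1, bp2, max_len)
            assert got == oracle_homology(seqs, bp1, bp2, max_len)

    def test_bounds_and_seq_length(self, toy_reference):
        rng = np.random.default_rng(19)
        for _ in range(200):
            p1, p2 = sorted(int(x) for x in rng.integers(100, 9_900, size=2))
            if p1 == p2:
                continue
            hom_len, hom_seq = homology_at_junction(
                toy_reference, Breakend("chr1", p1, "+"), Breakend("chr1", p2, "-"), 50
            )
            assert 0 <= hom_len <= min(50, p2 - p1)
            assert len(hom_seq) == hom_len

    def test_inversion_junction_mirror_symmetry(self, toy_reference):
        rng = np.random.default_rng(29)
        for _ in range(200):
            p1, p2 = sorted(int(x) for x in rng.integers(100, 9_900, size=2))
            if p1 == p2:
                continue
            a, _ = homology_at_junction(
                toy_reference, Breakend("chr1", p1, "+"), Breakend("chr1", p2, "+"), 30
            )
            b, _ = homology_at_junction(
                toy_reference, Breakend("chr1", p1, "-"), Breakend("chr1", p2, "-"), 30
            )
            assert a == b


class TestContainerLevel:
    def test_adds_homlen_for_every_paired_record(self, toy_reference):
        recs = [make_del(f"d{i}", pos1=1000 * (i + 1), pos2=1000 * (i + 1) + 500) for i in range(3)]
        c = build_container(recs)
        out = infer_microhomology(c, toy_reference, max_len=50)
        homlen = out.info_dict("homlen")
        assert set(homlen) == {"d0", "d1", "d2"}
        assert all(v[0] >= 0 for v in homlen.values())
        seqs = out.info_dict("homseq")
        for rid, (length,) in homlen.items():
            assert len(seqs.get(rid, [""])[0]) == length

    def test_missing_contig_listed(self, toy_reference):
        c = build_container([make_del("d0", chrom="chrZ")])
        with pytest.raises(SVTabError, match="chrZ"):
            infer_microhomology(c, toy_reference)

    def test_max_len_zero_yields_all_zero(self, toy_reference):
        c = build_container([make_del("d0", pos1=100, pos2=700)])
        out = infer_microhomology(c, toy_reference, max_len=0)
        assert out.info_dict("homlen") == {"d0": [0]}

    def test_junction_insertion_forces_zero(self, toy_reference):
        rec = make_del("d0", pos1=100, pos2=700, info={"insseq": "ACGT"})
        out = infer_microhomology(build_container([rec]), toy_reference, max_len=50)
        assert out.info_dict("homlen") == {"d0": [0]}

    def test_caller_homlen_preserved(self, toy_reference):
        rec = make_del("d0", pos1=100, pos2=700, info={"HOMLEN": 7, "HOMSEQ": "AAAAAAA"})
        out = infer_microhomology(build_container([rec]), toy_reference, max_len=10)
        assert out.info_dict("HOMLEN") == {"d0": [7]}
        assert "homlen" in out.infos
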