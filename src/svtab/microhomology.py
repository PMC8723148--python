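"""Microhomology inference at SV junctions from the reference genome.

Microhomology is a short stretch of identical sequence present on both
sides of an SV junction; its length distribution is evidence for the DNA
repair mechanism that created the variant (e.g. microhomology-mediated end
joining), which makes an accurate, strictly 1-based implementation matter.

The estimate is a two-way (junction-spanning) extension. For the canonical
deletion-type junction (strands +/-, positions p1 < p2):

* forward: the largest ``f <= max_len`` with
  ``ref[p1+1 .. p1+f] == ref[p2+1 .. p2+f]``;
* backward: the largest ``b <= max_len - f`` with
  ``ref[p1-b+1 .. p1] == ref[p2-b+1 .. p2]``;
* ``hom_len = f + b`` and ``hom_seq = ref[p1-b+1 .. p1+f]``.

Other strand combinations reduce to the same comparison by
reverse-complementing the flanks of any breakend whose strand differs from
the canonical one for its slot (bp1 '+', bp2 '-'), so an inversion junction
and its strand-flipped mirror give identical lengths. Comparison is
case-insensitive, 'N' never matches, windows are truncated at chromosome
ends, and for intrachromosomal events the result is capped at the SV
length (a deletion cannot exhibit more homology than it removes).
"""

from __future__ import annotations

from .datamodel import Breakend, SVContainer, SVTabError

__all__ = ["ReferenceGenome", "homology_at_junction", "infer_microhomology"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class ReferenceGenome:
    """Uniform 1-based-inclusive accessor over a FASTA file or a dict.

    Accepts a path to a FASTA file (indexed with pyfaidx), a pyfaidx.Fasta
    object, or a plain ``{chrom: sequence}`` mapping — the latter is handy
    in tests. Out-of-range requests are truncated to the chromosome, not
    errors.
    """

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {c: str(s) for c, s in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = source if isinstance(source, pyfaidx.Fasta) else pyfaidx.Fasta(str(source))
            self._seqs = None

    def contigs(self) -> list:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs()

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive range, truncated to bounds."""
        if chrom not in self:
            raise SVTabError(f"contig {chrom!r} absent from reference")
        start = max(start, 1)
        end = min(end, self.length(chrom))
        if start > end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1:end].upper()
        return str(self._fasta[chrom][start - 1:end]).upper()


def _streams(ref: ReferenceGenome, chrom: str, pos: int, mirrored: bool, max_len: int):
    """Forward/backward comparison streams for one breakend.

    Each stream lists bases in order of increasing distance from the
    junction; ``mirrored`` swaps and complements the two flanks so that a
    non-canonical strand reads like the canonical one.
    """
    right = ref.fetch(chrom, pos + 1, pos + max_len)
    left_rev = ref.fetch(chrom, pos - max_len + 1, pos)[::-1]
    if mirrored:
        return _complement(left_rev), _complement(right)
    return right, left_rev


def _common_prefix(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if n >= limit or x != y or x == "N" or y == "N":
            break
        n += 1
    return n


def homology_at_junction(
    ref: ReferenceGenome | dict,
    bp1: Breakend,
    bp2: Breakend,
    max_len: int = 200,
) -> tuple[int, str]:
    """Infer (hom_len, hom_seq) for one junction.

    ``hom_seq`` is reported in the frame of ``bp1`` (reverse-complemented
    reference sequence when bp1 is on the '-' strand); its length always
    equals ``hom_len``.
    """
    if max_len < 0:
        raise SVTabError(f"max_len must be >= 0, got {max_len}")
    if not isinstance(ref, ReferenceGenome):
        ref = ReferenceGenome(ref)
    for bp in (bp1, bp2):
        if bp.chrom not in ref:
            raise SVTabError(f"contig {bp.chrom!r} absent from reference")
    if max_len == 0:
        return 0, ""

    fwd1, bwd1 = _streams(ref, bp1.chrom, bp1.pos, mirrored=bp1.strand != "+", max_len=max_len)
    fwd2, bwd2 = _streams(ref, bp2.chrom, bp2.pos, mirrored=bp2.strand != "-", max_len=max_len)

    f = _common_prefix(fwd1, fwd2, max_len)
    b = _common_prefix(bwd1, bwd2, max_len - f)

    cap = max_len
    if bp1.chrom == bp2.chrom:
        cap = min(cap, abs(bp2.pos - bp1.pos))
    f = min(f, cap)
    b = min(b, cap - f)

    hom_seq = bwd1[:b][::-1] + fwd1[:f]
    return f + b, hom_seq


def infer_microhomology(
    container: SVContainer,
    ref,
    max_len: int = 200,
) -> SVContainer:
    """Annotate every two-breakend record with ``homlen``/``homseq`` INFO.

    Caller-provided HOMLEN/HOMSEQ INFO keys, when present, are preserved
    untouched under their original names. Records carrying a non-empty
    junction insertion (``insseq``) get ``homlen`` 0: a novel inserted
    sequence interrupts junction-spanning homology.
    """
    if not isinstance(ref, ReferenceGenome):
        ref = ReferenceGenome(ref)
    contigs = set(ref.contigs())
    needed = set()
    for r in container.positions.itertuples(index=False):
        needed.add(r.chrom1)
        if isinstance(r.chrom2, str):
            needed.add(r.chrom2)
    missing = sorted(needed - contigs)
    if missing:
        raise SVTabError(f"contig(s) absent from reference: {missing}")

    inserted = container.info_dict("insseq")
    homlens: dict = {}
    homseqs: dict = {}
    for rec in container.to_records():
        if rec.bp2 is None:
            continue
        ins = inserted.get(rec.id)
        if ins and str(ins[0]):
            homlens[rec.id] = 0
            continue
        hl, hs = homology_at_junction(ref, rec.bp1, rec.bp2, max_len=max_len)
        homlens[rec.id] = hl
        if hs:
            homseqs[rec.id] = hs
    out = container.add_info(
        "homlen", homlens, number="1", type_="Integer",
        description="Inferred microhomology length at the junction (bp)",
        overwrite=True,
    )
    return out.add_info(
        "homseq", homseqs, number="1", type_="String",
        description="Inferred microhomology sequence at the junction",
        overwrite=True,
    )
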