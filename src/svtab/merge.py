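"""Merge SV calls from multiple callers into consensus events.

Two records are linked — and end up in the same merged event — iff all
three of the following hold after normalization:

(i)   their breakend coordinates agree: in ``proximity`` mode both
      ``|pos1_a - pos1_b|`` and ``|pos2_a - pos2_b|`` are within the
      user threshold; in ``confidence_interval`` mode the CIPOS intervals
      around pos1 share at least 1 bp and likewise the intervals around
      pos2;
(ii)  the strands of both breakends are concordant;
(iii) for intrachromosomal records the spans ``[pos1, pos2]`` overlap by
      at least 1 bp (insertions span ``[pos1, pos1 + max(svlen, 1)]``;
      the condition is waived for interchromosomal pairs, whose span is
      undefined).

Conditions (ii) and (iii) prevent merging discordant SV types and nearby
but non-overlapping small events. Merged events are the transitive
closures (union-find) of the link relation, so a chain of pairwise-linked
records can span more than one threshold; each event is represented by
the record of the first caller (in input order) that supports it,
coordinates taken verbatim.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .datamodel import (
    MultiSVContainer,
    SVContainer,
    SVRecord,
    SVTabError,
    VCFHeader,
    _natural_key,
    build_container,
)

__all__ = ["MergeResult", "merge_containers", "filter_by_support"]

logger = logging.getLogger(__name__)


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass
class MergeResult:
    """Outcome of a multi-caller merge.

    ``container`` holds one representative record per merged event with
    INFO keys ``mergedid``, ``supportingcaller`` (list of caller labels),
    ``supportingcallercount`` and ``originalid_<caller>`` (source record
    ids). ``membership`` maps every input record to its merged event:
    columns (caller, record_id, mergedid).
    """

    container: SVContainer
    membership: pd.DataFrame
    callers: list

    def cluster_labels(self) -> dict:
        """(caller, record_id) -> mergedid for every merged input record."""
        return {
            (r.caller, r.record_id): r.mergedid
            for r in self.membership.itertuples(index=False)
        }


@dataclass
class _Rec:
    caller: str
    caller_idx: int
    order: int
    record: SVRecord

    @property
    def key(self):
        b1, b2 = self.record.bp1, self.record.bp2
        return (b1.chrom, b2.chrom, b1.strand, b2.strand)

    @property
    def intrachrom(self) -> bool:
        return self.record.bp1.chrom == self.record.bp2.chrom

    def span(self) -> tuple[int, int]:
        b1, b2 = self.record.bp1, self.record.bp2
        if self.record.svtype == "INS":
            return b1.pos, b1.pos + max(self.record.svlen or 1, 1)
        return b1.pos, b2.pos


def _linked(a: _Rec, b: _Rec, mode: str, threshold: int) -> bool:
    """The pairwise link predicate: conditions (i)-(iii) above."""
    ra, rb = a.record, b.record
    # (i) coordinate agreement per mode
    if mode == "proximity":
        if abs(ra.bp1.pos - rb.bp1.pos) > threshold:
            return False
        if abs(ra.bp2.pos - rb.bp2.pos) > threshold:
            return False
    else:
        if not _ci_overlap(ra.bp1, rb.bp1):
            return False
        if not _ci_overlap(ra.bp2, rb.bp2):
            return False
    # (ii) strand concordance is guaranteed by grouping on key; (iii) spans
    if a.intrachrom:
        lo_a, hi_a = a.span()
        lo_b, hi_b = b.span()
        if max(lo_a, lo_b) > min(hi_a, hi_b):
            return False
    return True


def _ci_overlap(x, y) -> bool:
    return max(x.pos + x.ci_lo, y.pos + y.ci_lo) <= min(x.pos + x.ci_hi, y.pos + y.ci_hi)


def merge_containers(
    inputs,
    mode: str = "proximity",
    threshold: int = 100,
) -> MergeResult:
    """Cluster records from >= 2 callers into merged events.

    ``inputs`` is an ordered mapping caller label -> container (or a
    :class:`~svtab.datamodel.MultiSVContainer`). ``threshold`` (bp) is
    used only in ``proximity`` mode. Records without a second breakend
    are skipped. Caller input order decides which record represents each
    event; cluster membership itself is order-independent.
    """
    if isinstance(inputs, MultiSVContainer):
        inputs = dict(inputs)
    if len(inputs) < 2:
        raise SVTabError(f"merge needs >= 2 input containers, got {len(inputs)}")
    if mode not in ("proximity", "confidence_interval"):
        raise SVTabError(f"unknown merge mode {mode!r}")
    if mode == "proximity" and threshold < 0:
        raise SVTabError(f"threshold must be >= 0, got {threshold}")

    callers = list(inputs)
    recs: list[_Rec] = []
    for ci, caller in enumerate(callers):
        for oi, record in enumerate(inputs[caller].to_records()):
            if record.bp2 is None:
                logger.info("skipping single-breakend record %s/%s", caller, record.id)
                continue
            recs.append(_Rec(caller, ci, oi, record))

    dsu = _DisjointSet(len(recs))
    # group by (chrom pair, strand pair); within a group, an interval tree
    # over the pos1 tolerance window proposes candidate pairs, and the full
    # predicate decides
    groups: dict = {}
    for i, r in enumerate(recs):
        groups.setdefault(r.key, []).append(i)
    for members in groups.values():
        tree = IntervalTree()
        for i in members:
            b1 = recs[i].record.bp1
            if mode == "proximity":
                # window [pos - t, pos + t]; overlap with another record's
                # point <=> |dpos1| <= t, so query the point, insert the window
                lo, hi = b1.pos - threshold, b1.pos + threshold + 1
                hits = tree.overlap(b1.pos, b1.pos + 1)
            else:
                lo, hi = b1.pos + b1.ci_lo, b1.pos + b1.ci_hi + 1
                hits = tree.overlap(lo, hi)
            for iv in hits:
                j = iv.data
                if _linked(recs[i], recs[j], mode, threshold):
                    dsu.union(i, j)
            tree.addi(lo, hi, i)

    clusters: dict = {}
    for i in range(len(recs)):
        clusters.setdefault(dsu.find(i), []).append(i)

    # deterministic event order: by representative's coordinates
    def cluster_sort_key(members):
        rep = min(members, key=lambda i: (recs[i].caller_idx, recs[i].order))
        b1, b2 = recs[rep].record.bp1, recs[rep].record.bp2
        return (_natural_key(b1.chrom), b1.pos, _natural_key(b2.chrom), b2.pos, rep)

    ordered = sorted(clusters.values(), key=cluster_sort_key)

    header = VCFHeader()
    for caller in callers:
        src = inputs[caller].header
        for name, length in src.contigs.items():
            header.contigs.setdefault(name, length)
        for k, v in src.infos.items():
            header.infos.setdefault(k, v)
    header.infos["mergedid"] = ("1", "String", "Merged event id")
    header.infos["supportingcaller"] = (".", "String", "Callers supporting the event")
    header.infos["supportingcallercount"] = ("1", "Integer", "Number of supporting callers")

    out_records = []
    mem_rows = []
    for mergedid, members in enumerate(ordered):
        members = sorted(members, key=lambda i: (recs[i].caller_idx, recs[i].order))
        rep = recs[members[0]]
        supporting = []
        originals: dict = {}
        for i in members:
            r = recs[i]
            if r.caller not in supporting:
                supporting.append(r.caller)
            originals.setdefault(r.caller, []).append(r.record.id)
            mem_rows.append((r.caller, r.record.id, mergedid))
        info = dict(rep.record.info)
        info["mergedid"] = str(mergedid)
        info["supportingcaller"] = supporting
        info["supportingcallercount"] = len(supporting)
        for caller, ids in originals.items():
            info[f"originalid_{caller}"] = ids
            header.infos.setdefault(
                f"originalid_{caller}", (".", "String", f"Source ids from {caller}")
            )
        out_records.append(
            SVRecord(
                id=f"merged_{mergedid}",
                bp1=rep.record.bp1,
                bp2=rep.record.bp2,
                svtype=rep.record.svtype,
                svlen=rep.record.svlen,
                qual=rep.record.qual,
                filter=list(rep.record.filter),
                info=info,
            )
        )

    membership = pd.DataFrame(mem_rows, columns=["caller", "record_id", "mergedid"])
    return MergeResult(
        container=build_container(out_records, header),
        membership=membership,
        callers=callers,
    )


def filter_by_support(result: MergeResult, min_callers: int) -> MergeResult:
    """Keep merged events supported by at least ``min_callers`` callers."""
    if min_callers < 1:
        raise SVTabError(f"min_callers must be >= 1, got {min_callers}")
    if min_callers > len(result.callers):
        warnings.warn(
            f"min_callers={min_callers} exceeds the number of input callers "
            f"({len(result.callers)}); result is empty",
            stacklevel=2,
        )
    counts = result.container.info_dict("supportingcallercount")
    keep_ids = [rid for rid, vals in counts.items() if vals[0] >= min_callers]
    container = result.container.subset(keep_ids)
    kept_events = {int(v[0]) for rid, v in result.container.info_dict("mergedid").items() if rid in set(keep_ids)}
    membership = result.membership[result.membership["mergedid"].isin(kept_events)]
    return MergeResult(container=container, membership=membership.reset_index(drop=True), callers=result.callers)
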