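"""Breakend annotation against BED files via per-chromosome interval trees.

Typical uses: flagging breakends that fall in common fragile sites (CFS),
attaching replication-timing zone labels, gene names or copy-number values.
Annotations become ordinary INFO tables (one per breakend, suffixes ``1``
and ``2``), so they can drive filtering and SV classification and are
exported to VCF/BEDPE like any other INFO key.

Membership convention: a 1-based breakend position ``p`` is inside the BED
interval ``[start, end)`` iff ``start < p <= end`` — i.e. exactly when the
0-based base ``p - 1`` lies in the interval.
"""

from __future__ import annotations

from pathlib import Path

from intervaltree import IntervalTree

from .datamodel import SVContainer, SVTabError

__all__ = ["IntervalIndex", "build_interval_index", "annotate_bed"]


class IntervalIndex:
    """Per-chromosome balanced interval trees over BED records.

    Payload of each interval is the BED name column (or ``True`` for BED3).
    Point and interval queries cost O(log n + k); duplicated and
    overlapping intervals are allowed and all hits are returned.
    """

    def __init__(self):
        self.trees: dict[str, IntervalTree] = {}
        self.n_intervals = 0

    def add(self, chrom: str, start0: int, end0: int, payload=True):
        if end0 <= start0:
            raise SVTabError(f"interval end ({end0}) must exceed start ({start0})")
        self.trees.setdefault(chrom, IntervalTree()).addi(start0, end0, payload)
        self.n_intervals += 1

    def __len__(self) -> int:
        return self.n_intervals

    def chromosomes(self) -> list:
        return list(self.trees)

    def query_point(self, chrom: str, pos1: int) -> list:
        """Payloads of intervals containing the 1-based position ``pos1``."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.at(pos1 - 1), key=lambda iv: (iv.begin, iv.end, str(iv.data)))
        return [iv.data for iv in hits]


def build_interval_index(bed_path) -> IntervalIndex:
    """Build an :class:`IntervalIndex` from a BED3+ file.

    Columns beyond the third are optional; column 4 (name), when present,
    becomes the interval payload used by value-mode annotation.
    """
    index = IntervalIndex()
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise SVTabError(f"{bed_path} line {lineno}: BED needs >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise SVTabError(
                f"{bed_path} line {lineno}: non-numeric coordinates"
            ) from exc
        if end <= start:
            raise SVTabError(
                f"{bed_path} line {lineno}: end ({end}) must exceed start ({start})"
            )
        payload = fields[3] if len(fields) > 3 else True
        index.add(chrom, start, end, payload)
    return index


def annotate_bed(
    container: SVContainer,
    index: IntervalIndex,
    name: str,
    mode: str = "presence",
    overwrite: bool = False,
) -> SVContainer:
    """Annotate both breakends of every record against an interval index.

    Adds two INFO tables, ``name + "1"`` and ``name + "2"`` (one per
    breakend). In ``presence`` mode the value is a boolean (any overlap of
    the breakend point); in ``value`` mode it is the payload(s) of the
    overlapping interval(s), stored long-form when several intervals
    overlap and omitted when none do. The breakend point itself (not its
    confidence interval) is the query locus.
    """
    if mode not in ("presence", "value"):
        raise SVTabError(f"unknown annotation mode {mode!r}; use 'presence' or 'value'")
    for suffix in ("1", "2"):
        if name + suffix in container.infos and not overwrite:
            raise SVTabError(
                f"INFO key {name + suffix!r} already exists (pass overwrite=True)"
            )

    out = container
    for suffix, chrom_col, pos_col in (("1", "chrom1", "pos1"), ("2", "chrom2", "pos2")):
        values: dict = {}
        for row in container.positions.itertuples(index=False):
            chrom = getattr(row, chrom_col)
            pos = getattr(row, pos_col)
            if chrom is None or (isinstance(chrom, float)):
                if mode == "presence":
                    values[row.id] = False
                continue
            hits = index.query_point(chrom, int(pos))
            if mode == "presence":
                values[row.id] = bool(hits)
            elif hits:
                values[row.id] = hits
        out = out.add_info(
            name + suffix,
            values,
            number="." if mode == "value" else "1",
            type_="String",
            description=f"{mode} annotation of breakend {suffix} ({name})",
            overwrite=overwrite,
        )
    return out
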