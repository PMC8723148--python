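"""Tidy linked-table container for structural variant (SV) calls.

An SV call set is stored as a set of rectangular tables linked by the SV
record identifier, following the tidy-data principles: each variable is a
column, each observation a row, and each type of observational unit its own
table. Multi-valued VCF INFO/FORMAT entries are therefore unpacked into long
form with an explicit ``value_index`` column instead of being packed into a
single comma-separated cell.

Tables held by :class:`SVContainer`:

``positions``
    one row per SV record: id, chrom1, pos1, strand1, chrom2, pos2,
    strand2, qual, svtype.
``filters``
    long form (id, filter), one row per FILTER entry.
``infos``
    mapping INFO key -> long-form table (id, value_index, value).
``formats``
    long form (id, sample, key, value_index, value).
``header``
    contig names/lengths, INFO/FORMAT declarations and sample names.

Coordinates are 1-based VCF-style throughout; conversion to 0-based
half-open happens only at the BED/BEDPE boundary (module :mod:`svtab.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Breakend",
    "SVRecord",
    "VCFHeader",
    "SVContainer",
    "MultiSVContainer",
    "build_container",
    "SVTabError",
    "UnknownIdError",
    "DuplicateIdError",
    "UnknownInfoError",
]

POSITION_COLUMNS = [
    "id",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
    "qual",
    "svtype",
]
INFO_COLUMNS = ["id", "value_index", "value"]
FILTER_COLUMNS = ["id", "filter"]
FORMAT_COLUMNS = ["id", "sample", "key", "value_index", "value"]

SVTYPES = {"DEL", "DUP", "INV", "INS", "BND"}


class SVTabError(Exception):
    """Base class for svtab errors."""


class DuplicateIdError(SVTabError):
    pass


class UnknownIdError(SVTabError):
    pass


class UnknownInfoError(SVTabError, KeyError):
    pass


def _natural_key(chrom: str) -> tuple:
    """Sort chromosomes naturally: chr2 < chr10 < chrX."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Breakend:
    """One endpoint of an SV junction.

    ``strand`` encodes which side of the breakpoint is retained in the
    derivative chromosome: ``'+'`` means the segment extending left of
    ``pos`` is retained (``pos`` is the last retained base), ``'-'`` means
    the segment extending right of ``pos`` is retained (``pos`` is the
    first retained base). ``ci_lo``/``ci_hi`` are confidence-interval
    offsets in bp relative to ``pos`` (CIPOS/CIEND in VCF).
    """

    chrom: str
    pos: int
    strand: str
    ci_lo: int = 0
    ci_hi: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.ci_lo > self.ci_hi:
            raise ValueError(f"ci_lo ({self.ci_lo}) > ci_hi ({self.ci_hi})")


@dataclass
class SVRecord:
    """One SV event: a pair of breakends plus type, length and quality.

    Intrachromosomal records are canonically ordered ``bp1.pos <= bp2.pos``;
    interchromosomal records by natural chromosome order. ``svlen`` is
    defined only for intrachromosomal events (``pos2 - pos1`` for
    DEL/DUP/INV). ``bp2`` may be ``None`` for single breakends (e.g. Gridss
    unpartnered records); such records are excluded from merging and
    classification by default.
    """

    id: str
    bp1: Breakend
    bp2: Breakend | None
    svtype: str
    svlen: int | None = None
    qual: float | None = None
    filter: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.bp2 is not None:
            self._canonicalize()
        if self.svlen is not None and self.svlen < 0:
            raise ValueError(f"svlen must be non-negative, got {self.svlen}")

    def _canonicalize(self):
        b1, b2 = self.bp1, self.bp2
        if b1.chrom == b2.chrom:
            if b1.pos > b2.pos:
                self.bp1, self.bp2 = b2, b1
            if self.svlen is None and self.svtype in ("DEL", "DUP", "INV"):
                self.svlen = self.bp2.pos - self.bp1.pos
        else:
            if _natural_key(b1.chrom) > _natural_key(b2.chrom):
                self.bp1, self.bp2 = b2, b1
            if self.svlen is not None:
                raise ValueError(
                    f"record {self.id}: svlen defined for interchromosomal event"
                )

    @property
    def is_intrachromosomal(self) -> bool:
        return self.bp2 is not None and self.bp1.chrom == self.bp2.chrom


@dataclass
class VCFHeader:
    """Header metadata: contigs, INFO/FORMAT declarations, sample names.

    INFO/FORMAT declarations map key -> (number, type, description) where
    number and type follow VCF conventions ('1', 'A', '.', / 'Integer',
    'Float', 'String', 'Flag').
    """

    contigs: dict = field(default_factory=dict)  # name -> length or None
    infos: dict = field(default_factory=dict)  # key -> (number, type, descr)
    formats: dict = field(default_factory=dict)
    samples: list = field(default_factory=list)
    filters: dict = field(default_factory=dict)  # id -> description

    def copy(self) -> "VCFHeader":
        return VCFHeader(
            contigs=dict(self.contigs),
            infos=dict(self.infos),
            formats=dict(self.formats),
            samples=list(self.samples),
            filters=dict(self.filters),
        )


def _empty_positions() -> pd.DataFrame:
    return pd.DataFrame(columns=POSITION_COLUMNS)


def _long_table(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=INFO_COLUMNS)


class SVContainer:
    """One sample's SV calls as tidy linked tables keyed by record id."""

    def __init__(
        self,
        positions: pd.DataFrame,
        filters: pd.DataFrame | None = None,
        infos: Mapping[str, pd.DataFrame] | None = None,
        formats: pd.DataFrame | None = None,
        header: VCFHeader | None = None,
    ):
        self.positions = positions.reset_index(drop=True)
        self.filters = (
            filters.reset_index(drop=True)
            if filters is not None
            else pd.DataFrame(columns=FILTER_COLUMNS)
        )
        self.infos = {k: v.reset_index(drop=True) for k, v in (infos or {}).items()}
        self.formats = (
            formats.reset_index(drop=True)
            if formats is not None
            else pd.DataFrame(columns=FORMAT_COLUMNS)
        )
        self.header = header if header is not None else VCFHeader()
        self._validate()

    # ------------------------------------------------------------------ #
    def _validate(self):
        ids = self.positions["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DuplicateIdError(f"duplicate record id {dup!r}")
        known = set(ids)
        for key, tab in self.infos.items():
            unknown = set(tab["id"]) - known
            if unknown:
                raise UnknownIdError(
                    f"INFO table {key!r} references unknown id(s): {sorted(unknown)}"
                )
        for name, tab in (("filters", self.filters), ("formats", self.formats)):
            unknown = set(tab["id"]) - known
            if unknown:
                raise UnknownIdError(
                    f"{name} table references unknown id(s): {sorted(unknown)}"
                )

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.positions)

    @property
    def ids(self) -> list:
        return list(self.positions["id"])

    def __repr__(self) -> str:
        return (
            f"SVContainer({len(self)} records, "
            f"{len(self.infos)} INFO tables, "
            f"{len(self.header.samples)} samples)"
        )

    # -- INFO access ---------------------------------------------------- #
    def info_keys(self) -> list:
        return list(self.infos)

    def get_info(self, name: str) -> pd.DataFrame:
        """Return a copy of the long-form table for one INFO key.

        Raises :class:`UnknownInfoError` listing the available keys if the
        key is not declared.
        """
        if name not in self.infos:
            raise UnknownInfoError(
                f"unknown INFO key {name!r}; available: {sorted(self.infos)}"
            )
        return self.infos[name].copy()

    def add_info(
        self,
        name: str,
        values: Mapping,
        *,
        number: str = ".",
        type_: str = "String",
        description: str = "",
        overwrite: bool = False,
    ) -> "SVContainer":
        """Return a new container with an extra INFO table.

        ``values`` maps record id -> scalar or list of values. Scalars are
        stored at ``value_index`` 0; lists are exploded long-form. The
        header gains a matching INFO declaration, so the key is exported
        when the container is written back to VCF or BEDPE.
        """
        if name in self.infos and not overwrite:
            raise SVTabError(
                f"INFO key {name!r} already exists (pass overwrite=True to replace)"
            )
        known = set(self.positions["id"])
        unknown = set(values) - known
        if unknown:
            raise UnknownIdError(f"unknown record id(s): {sorted(unknown)}")
        rows = []
        for rid, val in values.items():
            vals = val if isinstance(val, (list, tuple)) else [val]
            for i, v in enumerate(vals):
                rows.append((rid, i, v))
        # preserve positions-table order for reproducible output
        order = {rid: i for i, rid in enumerate(self.positions["id"])}
        rows.sort(key=lambda r: (order[r[0]], r[1]))
        new_infos = dict(self.infos)
        new_infos[name] = _long_table(rows)
        header = self.header.copy()
        header.infos[name] = (number, type_, description or f"svtab INFO {name}")
        return SVContainer(self.positions, self.filters, new_infos, self.formats, header)

    def info_dict(self, name: str) -> dict:
        """INFO values as id -> list-of-values (empty dict if key absent)."""
        if name not in self.infos:
            return {}
        out: dict = {}
        tab = self.infos[name]
        for rid, _, val in tab.itertuples(index=False):
            out.setdefault(rid, []).append(val)
        return out

    # -- subsetting ----------------------------------------------------- #
    def subset(self, ids: Iterable) -> "SVContainer":
        """Subset to the given ids, preserving positions-table order."""
        keep = set(ids)
        pos = self.positions[self.positions["id"].isin(keep)]
        filt = self.filters[self.filters["id"].isin(keep)]
        infos = {k: t[t["id"].isin(keep)] for k, t in self.infos.items()}
        fmts = self.formats[self.formats["id"].isin(keep)]
        return SVContainer(pos, filt, infos, fmts, self.header.copy())

    # -- record extraction ---------------------------------------------- #
    def to_records(self) -> list:
        """Rebuild :class:`SVRecord` objects from the linked tables."""
        cipos = self.info_dict("cipos")
        ciend = self.info_dict("ciend")
        svlen = self.info_dict("svlen")
        filt_map: dict = {}
        for rid, f in self.filters.itertuples(index=False):
            filt_map.setdefault(rid, []).append(f)
        canonical = {"svtype", "svlen", "cipos", "ciend"}
        extra_keys = [k for k in self.infos if k not in canonical]
        extras = {k: self.info_dict(k) for k in extra_keys}
        records = []
        for row in self.positions.itertuples(index=False):
            rid = row.id
            c1 = cipos.get(rid, [0, 0])
            c2 = ciend.get(rid, [0, 0])
            bp1 = Breakend(row.chrom1, int(row.pos1), row.strand1, int(c1[0]), int(c1[1]))
            bp2 = None
            if not _is_missing(row.chrom2):
                bp2 = Breakend(row.chrom2, int(row.pos2), row.strand2, int(c2[0]), int(c2[1]))
            sl = svlen.get(rid)
            qual = None if _is_missing(row.qual) else float(row.qual)
            info = {k: extras[k][rid] for k in extra_keys if rid in extras[k]}
            records.append(
                SVRecord(
                    id=rid,
                    bp1=bp1,
                    bp2=bp2,
                    svtype=row.svtype,
                    svlen=None if sl is None else int(sl[0]),
                    qual=qual,
                    filter=filt_map.get(rid, []),
                    info=info,
                )
            )
        return records


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def build_container(
    records: Sequence[SVRecord],
    header: VCFHeader | None = None,
    formats: pd.DataFrame | None = None,
) -> SVContainer:
    """Assemble an :class:`SVContainer` from normalized SV records.

    Canonical per-record attributes become INFO tables (``svtype``,
    ``svlen``, ``cipos``, ``ciend``); caller-specific extras carried in
    ``record.info`` become additional long-form tables.
    """
    header = header.copy() if header is not None else VCFHeader()
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)

    pos_rows = []
    filt_rows = []
    info_rows: dict[str, list] = {"svtype": [], "svlen": [], "cipos": [], "ciend": []}
    fmt_rows = []
    for rec in records:
        b1, b2 = rec.bp1, rec.bp2
        pos_rows.append(
            (
                rec.id,
                b1.chrom,
                b1.pos,
                b1.strand,
                b2.chrom if b2 else None,
                b2.pos if b2 else None,
                b2.strand if b2 else None,
                rec.qual,
                rec.svtype,
            )
        )
        for f in rec.filter:
            filt_rows.append((rec.id, f))
        info_rows["svtype"].append((rec.id, 0, rec.svtype))
        if rec.svlen is not None:
            info_rows["svlen"].append((rec.id, 0, rec.svlen))
        info_rows["cipos"].append((rec.id, 0, b1.ci_lo))
        info_rows["cipos"].append((rec.id, 1, b1.ci_hi))
        if b2 is not None:
            info_rows["ciend"].append((rec.id, 0, b2.ci_lo))
            info_rows["ciend"].append((rec.id, 1, b2.ci_hi))
        for key, val in rec.info.items():
            vals = val if isinstance(val, (list, tuple)) else [val]
            rows = info_rows.setdefault(key, [])
            for i, v in enumerate(vals):
                rows.append((rec.id, i, v))

    positions = pd.DataFrame(pos_rows, columns=POSITION_COLUMNS)
    if positions.empty:
        positions = _empty_positions()
    filters = pd.DataFrame(filt_rows, columns=FILTER_COLUMNS)
    infos = {k: _long_table(v) for k, v in info_rows.items() if v or k == "svtype"}

    for key, (num, typ, desc) in _CANONICAL_INFO_META.items():
        header.infos.setdefault(key, (num, typ, desc))
    for key in infos:
        header.infos.setdefault(key, (".", "String", f"svtab INFO {key}"))

    if formats is None:
        formats = pd.DataFrame(fmt_rows, columns=FORMAT_COLUMNS)
    return SVContainer(positions, filters, infos, formats, header)


_CANONICAL_INFO_META = {
    "svtype": ("1", "String", "Type of structural variant"),
    "svlen": ("1", "Integer", "Length of the structural variant"),
    "cipos": ("2", "Integer", "Confidence interval around POS"),
    "ciend": ("2", "Integer", "Confidence interval around END"),
}


class MultiSVContainer:
    """Ordered collection of SVContainers keyed by sample (or caller) label."""

    def __init__(self, members: Mapping[str, SVContainer] | None = None):
        self.members: dict[str, SVContainer] = {}
        for label, container in (members or {}).items():
            self.add(label, container)

    def add(self, label: str, container: SVContainer):
        if label in self.members:
            raise SVTabError(f"duplicate label {label!r}")
        self.members[label] = container

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.items())

    def __getitem__(self, label: str) -> SVContainer:
        return self.members[label]

    def labels(self) -> list:
        return list(self.members)

    def __repr__(self) -> str:
        return f"MultiSVContainer({len(self)} members)"
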