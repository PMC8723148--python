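"""Declarative filtering of SV records on coordinates, INFO and FORMAT.

Conditions are strings of the form ``"item op value"``, e.g.
``"svlen > 50000"``, ``"svtype == DEL"``, ``"svtype in DEL,DUP"``.
``item`` is one of the canonical fields (``svtype``, ``svlen``, ``qual``,
``filter``) or any INFO key; ``op`` is one of ``== != < <= > >= in
not in``. Multiple conditions combine as a conjunction; disjunction is
expressed by filtering twice and taking the id-union with :func:`union`.

Multi-valued INFO follows VCF semantics: a comparison holds if ANY stored
value satisfies it. A record with no value for the queried key fails
positive comparisons (``==``, ``<`` ...) and passes negative ones
(``!=``, ``not in``).
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from .datamodel import SVContainer, SVTabError

__all__ = [
    "parse_condition",
    "filter_by_info",
    "filter_by_region",
    "filter_by_format",
    "matching_ids",
    "union",
]

logger = logging.getLogger(__name__)

_OPS = ("==", "!=", "<=", ">=", "<", ">", "not in", "in")
_COND_RE = re.compile(
    r"^\s*(?P<item>\S+)\s+(?P<op>==|!=|<=|>=|<|>|not\s+in|in)\s+(?P<value>.+?)\s*$"
)

_CANONICAL_ITEMS = ("svtype", "svlen", "qual", "filter")


def parse_condition(condition: str) -> tuple:
    """Split ``"item op value"`` into its three parts.

    The value keeps its textual form; coercion to number/bool happens at
    comparison time against each stored value.
    """
    m = _COND_RE.match(condition)
    if m is None:
        raise SVTabError(
            f"cannot parse condition {condition!r}; expected 'item op value' "
            f"with op in {_OPS}"
        )
    op = re.sub(r"\s+", " ", m.group("op"))
    return m.group("item"), op, m.group("value")


def _coerce_pair(stored, target: str):
    """Coerce the textual target to the stored value's type when possible."""
    if isinstance(stored, bool):
        return stored, target.lower() in ("true", "1", "yes")
    if isinstance(stored, (int, float)):
        try:
            return float(stored), float(target)
        except ValueError:
            raise SVTabError(
                f"type-incompatible comparison: numeric value {stored!r} vs {target!r}"
            )
    # stored is a string (or None-ish): numeric-looking pairs compare as numbers
    try:
        return float(stored), float(target)
    except (TypeError, ValueError):
        return str(stored), target


def _compare(stored, op: str, target: str) -> bool:
    if op == "in" or op == "not in":
        targets = [t.strip() for t in target.split(",")]
        hit = any(str(stored) == t or _num_eq(stored, t) for t in targets)
        return hit if op == "in" else not hit
    a, b = _coerce_pair(stored, target)
    if op == "==":
        return a == b
    if op == "!=":
        return a != b
    if isinstance(a, str) or isinstance(b, str):
        raise SVTabError(
            f"type-incompatible comparison: {op!r} on non-numeric value {stored!r}"
        )
    return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b}[op]


def _num_eq(stored, target: str) -> bool:
    try:
        return float(stored) == float(target)
    except (TypeError, ValueError):
        return False


def _values_for(container: SVContainer, item: str) -> dict:
    """id -> list of stored values for one queryable item."""
    if item == "svtype":
        return {r.id: [r.svtype] for r in container.positions.itertuples(index=False)}
    if item == "qual":
        return {
            r.id: [r.qual]
            for r in container.positions.itertuples(index=False)
            if r.qual is not None and r.qual == r.qual
        }
    if item == "filter":
        out: dict = {}
        for rid, f in container.filters.itertuples(index=False):
            out.setdefault(rid, []).append(f)
        return out
    if item in container.infos:
        return container.info_dict(item)
    if item == "svlen":
        return container.info_dict("svlen")
    known = sorted(set(_CANONICAL_ITEMS) | set(container.infos))
    raise SVTabError(f"unknown filter item {item!r}; known items: {known}")


def matching_ids(container: SVContainer, condition: str) -> set:
    """Ids of records satisfying a single condition."""
    item, op, target = parse_condition(condition)
    values = _values_for(container, item)
    negative = op in ("!=", "not in")
    result = set()
    for rid in container.positions["id"]:
        vals = values.get(rid)
        if not vals:
            if negative:
                result.add(rid)
            continue
        # ANY-value semantics, uniformly for positive and negative ops
        if any(_compare(v, op, target) for v in vals):
            result.add(rid)
    return result


def filter_by_info(container: SVContainer, conditions) -> SVContainer:
    """Keep records satisfying ALL conditions (conjunction).

    ``conditions`` is a single condition string or a list of them.
    Returns a new container; all linked tables are subset consistently.
    """
    if isinstance(conditions, str):
        conditions = [conditions]
    keep = set(container.positions["id"])
    for cond in conditions:
        keep &= matching_ids(container, cond)
    return container.subset(keep)


def filter_by_region(
    container: SVContainer,
    chrom: str,
    start: int,
    end: int,
    which: str = "either",
) -> SVContainer:
    """Keep records whose breakend position(s) fall in ``[start, end]``.

    ``which`` selects the breakend(s) that must lie in the (1-based,
    inclusive) region: ``bp1``, ``bp2``, ``either`` or ``both``. An unknown
    chromosome yields an empty result (logged), not an error.
    """
    if start > end:
        raise SVTabError(f"region start ({start}) > end ({end})")
    if which not in ("bp1", "bp2", "either", "both"):
        raise SVTabError(f"unknown 'which' {which!r}")
    known_chroms = set(container.positions["chrom1"]) | {
        c for c in container.positions["chrom2"] if isinstance(c, str)
    }
    if chrom not in known_chroms:
        logger.info("region chromosome %r not present in container", chrom)

    def inside(c, p) -> bool:
        return isinstance(c, str) and c == chrom and start <= p <= end

    keep = []
    for r in container.positions.itertuples(index=False):
        in1 = inside(r.chrom1, r.pos1)
        in2 = r.chrom2 is not None and not (
            isinstance(r.chrom2, float)
        ) and inside(r.chrom2, r.pos2)
        ok = {
            "bp1": in1,
            "bp2": in2,
            "either": in1 or in2,
            "both": in1 and in2,
        }[which]
        if ok:
            keep.append(r.id)
    return container.subset(keep)


def filter_by_format(
    container: SVContainer, sample: str, key: str, op: str, value
) -> SVContainer:
    """Keep records whose FORMAT value for (sample, key) satisfies op value."""
    fmts = container.formats
    if sample not in set(fmts["sample"]):
        raise SVTabError(f"unknown sample {sample!r}; known: {sorted(set(fmts['sample']))}")
    if key not in set(fmts["key"]):
        raise SVTabError(f"unknown FORMAT key {key!r}; known: {sorted(set(fmts['key']))}")
    if op not in _OPS:
        raise SVTabError(f"unknown operator {op!r}")
    sub = fmts[(fmts["sample"] == sample) & (fmts["key"] == key)]
    values: dict = {}
    for rid, _, _, _, val in sub.itertuples(index=False):
        values.setdefault(rid, []).append(val)
    negative = op in ("!=", "not in")
    keep = []
    for rid in container.positions["id"]:
        vals = values.get(rid)
        if not vals:
            if negative:
                keep.append(rid)
            continue
        if any(_compare(v, op, str(value)) for v in vals):
            keep.append(rid)
    return container.subset(keep)


def union(*containers: SVContainer) -> SVContainer:
    """Id-union of subsets of the same parent container.

    The first container's tables provide the base; records present only in
    later containers are appended in their order of first appearance. This
    is the set-op companion of the conjunctive condition grammar: OR two
    filters by uniting their results.
    """
    if not containers:
        raise SVTabError("union() needs at least one container")
    base = containers[0]
    pos = pd.concat([c.positions for c in containers], ignore_index=True)
    pos = pos.drop_duplicates(subset="id", keep="first")
    filt = pd.concat([c.filters for c in containers], ignore_index=True).drop_duplicates()
    keys: list = []
    for c in containers:
        keys += [k for k in c.infos if k not in keys]
    infos = {}
    for k in keys:
        tabs = [c.infos[k] for c in containers if k in c.infos]
        tab = pd.concat(tabs, ignore_index=True).drop_duplicates(
            subset=["id", "value_index"], keep="first"
        )
        infos[k] = tab
    fmts = pd.concat([c.formats for c in containers], ignore_index=True).drop_duplicates(
        subset=["id", "sample", "key", "value_index"], keep="first"
    )
    header = base.header.copy()
    for c in containers[1:]:
        for k, v in c.header.infos.items():
            header.infos.setdefault(k, v)
    return SVContainer(pos, filt, infos, fmts, header)
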