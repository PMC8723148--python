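"""Read and write SV call files: four caller VCF dialects plus BEDPE.

Supported callers: Manta, Delly, Lumpy and Gridss, each with its own way of
encoding breakend orientation (Manta INV3/INV5 flags, Delly CT, Lumpy
STRANDS, Gridss bracket-notation breakends only). ``read_vcf`` normalizes
all of them into the tidy :class:`~svtab.datamodel.SVContainer` model:

* one record per SV event — BND mate pairs are collapsed onto the mate with
  the smaller (chromosome, position);
* strands per the breakend convention of :class:`~svtab.datamodel.Breakend`
  (DEL = +/-, DUP = -/+, INV = ++ or --);
* CIPOS/CIEND mapped to per-breakend confidence intervals, (0, 0) when the
  caller reports none;
* every original INFO key kept as a long-form table.

``write_vcf`` emits a caller-neutral dialect (SVTYPE/END/SVLEN/CIPOS/CIEND
plus a two-character STRANDS key; BND events re-expanded to mate pairs with
MATEID) that ``read_vcf(..., caller="generic")`` reads back losslessly.

BEDPE coordinates are 0-based half-open; they are converted to 1-based at
this boundary and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import pysam

from .datamodel import (
    FORMAT_COLUMNS,
    Breakend,
    SVContainer,
    SVRecord,
    SVTabError,
    VCFHeader,
    _natural_key,
    build_container,
)

__all__ = [
    "read_vcf",
    "read_bedpe",
    "write_vcf",
    "write_bedpe",
    "parse_breakend_alt",
    "CALLERS",
]

CALLERS = ("manta", "delly", "lumpy", "gridss", "generic")

# INFO keys consumed by normalization; everything else passes through.
_CONSUMED_INFO = {
    "SVTYPE", "SVLEN", "END", "CIPOS", "CIEND", "CHR2", "POS2", "MATEID",
}

_BND_RE = {
    # t[p[ : local '+' (piece left of POS retained), mate '-'
    "t[p[": re.compile(r"^(?P<t>[A-Za-z]*)\[(?P<chrom>[^:\[\]]+):(?P<pos>\d+)\[$"),
    # t]p] : local '+', mate '+'
    "t]p]": re.compile(r"^(?P<t>[A-Za-z]*)\](?P<chrom>[^:\[\]]+):(?P<pos>\d+)\]$"),
    # ]p]t : local '-', mate '+'
    "]p]t": re.compile(r"^\](?P<chrom>[^:\[\]]+):(?P<pos>\d+)\](?P<t>[A-Za-z]*)$"),
    # [p[t : local '-', mate '-'
    "[p[t": re.compile(r"^\[(?P<chrom>[^:\[\]]+):(?P<pos>\d+)\[(?P<t>[A-Za-z]*)$"),
}

_BND_STRANDS = {"t[p[": ("+", "-"), "t]p]": ("+", "+"), "]p]t": ("-", "+"), "[p[t": ("-", "-")}

_DEFAULT_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+"), "INS": ("+", "-")}

_CT_STRANDS = {
    "3to5": ("+", "-"),
    "5to3": ("-", "+"),
    "3to3": ("+", "+"),
    "5to5": ("-", "-"),
}


def parse_breakend_alt(alt: str, local_chrom: str, local_pos: int, ref: str = "N"):
    """Parse a VCF breakend ALT string.

    Returns ``(mate_chrom, mate_pos, strand_local, strand_mate,
    inserted_seq)``. ``inserted_seq`` is the novel sequence inserted at the
    junction (the part of the ``t`` segment beyond the REF allele), empty
    for a clean junction.

    The four bracket forms map to strand pairs as follows (strand '+' means
    the segment to the left of the position is retained in the derivative):
    ``t[p[`` -> (+,-), ``t]p]`` -> (+,+), ``]p]t`` -> (-,+),
    ``[p[t`` -> (-,-).
    """
    for form, rx in _BND_RE.items():
        m = rx.match(alt)
        if m is None:
            continue
        t = m.group("t")
        strand_local, strand_mate = _BND_STRANDS[form]
        # per VCF the t segment carries the REF allele at its outer end;
        # anything beyond it is novel inserted sequence
        if form in ("t[p[", "t]p]"):
            inserted = t[len(ref):] if len(t) > len(ref) else ""
        else:
            inserted = t[: len(t) - len(ref)] if len(t) > len(ref) else ""
        return m.group("chrom"), int(m.group("pos")), strand_local, strand_mate, inserted
    raise SVTabError(f"malformed breakend ALT {alt!r} at {local_chrom}:{local_pos}")


# --------------------------------------------------------------------------- #
# VCF reading
# --------------------------------------------------------------------------- #

def _info_to_plain(value):
    """Convert a pysam INFO value to a plain scalar or list."""
    if isinstance(value, tuple):
        return [v for v in value]
    return value


def _header_from_pysam(vf: pysam.VariantFile) -> VCFHeader:
    header = VCFHeader()
    for name, ctg in vf.header.contigs.items():
        header.contigs[name] = ctg.length
    for key, rec in vf.header.info.items():
        header.infos[key] = (str(rec.number), rec.type, rec.description or "")
    for key, rec in vf.header.formats.items():
        header.formats[key] = (str(rec.number), rec.type, rec.description or "")
    for key, rec in vf.header.filters.items():
        if key != "PASS":
            header.filters[key] = rec.description or ""
    header.samples = list(vf.header.samples)
    return header


def _strands_for(caller: str, svtype: str, info: dict, rec_id: str):
    """Resolve breakend strands from caller-specific orientation fields."""
    if caller == "delly" and "CT" in info:
        ct = info["CT"]
        ct = ct[0] if isinstance(ct, list) else ct
        if ct not in _CT_STRANDS:
            raise SVTabError(f"record {rec_id}: unknown Delly CT value {ct!r}")
        return _CT_STRANDS[ct]
    if caller in ("lumpy", "generic") and "STRANDS" in info:
        val = info["STRANDS"]
        val = val[0] if isinstance(val, list) else val
        s = str(val)[:2]
        if not (s[0] in "+-" and s[1] in "+-"):
            raise SVTabError(f"record {rec_id}: unparseable STRANDS value {val!r}")
        return s[0], s[1]
    if caller == "generic" and "CT" in info:
        ct = info["CT"]
        ct = ct[0] if isinstance(ct, list) else ct
        if ct in _CT_STRANDS:
            return _CT_STRANDS[ct]
    if svtype == "INV":
        if info.get("INV3"):
            return "+", "+"
        if info.get("INV5"):
            return "-", "-"
    if svtype in _DEFAULT_STRANDS:
        return _DEFAULT_STRANDS[svtype]
    raise SVTabError(f"record {rec_id}: cannot resolve strands for SVTYPE={svtype}")


def _format_rows(rec, rec_id: str, samples) -> list:
    rows = []
    for sample in samples:
        sv = rec.samples[sample]
        for key in sv.keys():
            val = sv[key]
            if key == "GT":
                sep = "|" if getattr(sv, "phased", False) else "/"
                txt = sep.join("." if a is None else str(a) for a in val)
                rows.append((rec_id, sample, key, 0, txt))
                continue
            vals = val if isinstance(val, tuple) else (val,)
            for i, v in enumerate(vals):
                if v is None:
                    continue
                rows.append((rec_id, sample, key, i, v))
    return rows


def read_vcf(path, caller: str) -> SVContainer:
    """Read an SV VCF produced by one of the supported callers.

    BND mate pairs are collapsed to a single record keyed by the
    lower-coordinate mate; Gridss intrachromosomal breakend pairs are
    re-typed to DEL/DUP/INV from their strand combination so that the same
    event parses identically across callers. A BND record whose MATEID
    partner is absent raises an error naming the orphan.
    """
    caller = caller.lower()
    if caller not in CALLERS:
        raise SVTabError(f"unknown caller {caller!r}; expected one of {CALLERS}")
    vf = pysam.VariantFile(str(path))
    header = _header_from_pysam(vf)
    samples = header.samples

    raw = []
    auto_id = 0
    for rec in vf:
        rid = rec.id
        if rid is None:
            rid = f"sv_{auto_id}"
            auto_id += 1
        info = {k: _info_to_plain(v) for k, v in rec.info.items()}
        raw.append(
            dict(
                id=rid,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref or "N",
                alt=(rec.alts[0] if rec.alts else "."),
                qual=rec.qual,
                filter=[f for f in rec.filter.keys() if f != "PASS"],
                info=info,
                stop=rec.stop,
                fmt=_format_rows(rec, rid, samples),
            )
        )
    vf.close()

    records: list[SVRecord] = []
    fmt_rows: list = []
    bnd_like = {}
    order = []
    for r in raw:
        svtype = r["info"].get("SVTYPE")
        is_bracket = "[" in r["alt"] or "]" in r["alt"]
        # Delly-style translocations are one line with CHR2/END, no brackets;
        # they take the symbolic path like DEL/DUP/INV
        if is_bracket or (svtype == "BND" and "CHR2" not in r["info"]):
            bnd_like[r["id"]] = r
            order.append(("bnd", r["id"]))
        else:
            order.append(("sym", r["id"]))
            records_entry = _symbolic_record(r, caller)
            records.append(records_entry)
            fmt_rows.extend(r["fmt"])

    # pair BND mates
    consumed = set()
    bnd_records = {}
    for rid, r in bnd_like.items():
        if rid in consumed:
            continue
        alt = r["alt"]
        if "[" not in alt and "]" not in alt:
            # single breakend (Gridss '.'-terminated ALT): keep with bp2 absent
            bp1 = _local_breakend(r, strand=("+" if not alt.startswith(".") else "-"))
            rec = SVRecord(
                id=rid, bp1=bp1, bp2=None, svtype="BND", qual=r["qual"],
                filter=r["filter"], info=_extras(r["info"]),
            )
            bnd_records[rid] = rec
            fmt_rows.extend(r["fmt"])
            consumed.add(rid)
            continue
        mateid = r["info"].get("MATEID")
        mateid = mateid[0] if isinstance(mateid, list) else mateid
        if mateid is None or mateid not in bnd_like:
            raise SVTabError(f"BND record {rid!r} has no MATEID partner in file")
        mate = bnd_like[mateid]
        # keep the mate with the smaller (chrom, pos)
        key_r = (_natural_key(r["chrom"]), r["pos"], rid)
        key_m = (_natural_key(mate["chrom"]), mate["pos"], mateid)
        first, second = (r, mate) if key_r <= key_m else (mate, r)
        consumed.add(rid)
        consumed.add(mateid)
        mc, mp, s_local, s_mate, inserted = parse_breakend_alt(
            first["alt"], first["chrom"], first["pos"], first["ref"]
        )
        if (mc, mp) != (second["chrom"], second["pos"]):
            raise SVTabError(
                f"BND pair {first['id']}/{second['id']}: ALT coordinates "
                f"{mc}:{mp} do not match partner record"
            )
        ci1 = _ci(first["info"].get("CIPOS"))
        ci2 = _ci(second["info"].get("CIPOS", first["info"].get("CIEND")))
        bp1 = Breakend(first["chrom"], first["pos"], s_local, *ci1)
        bp2 = Breakend(mc, mp, s_mate, *ci2)
        if bp1.chrom == bp2.chrom:
            svtype = _svtype_from_strands(s_local, s_mate)
        else:
            svtype = "BND"
        extras = _extras(first["info"])
        if inserted:
            extras["insseq"] = inserted
        rec = SVRecord(
            id=first["id"], bp1=bp1, bp2=bp2, svtype=svtype,
            qual=first["qual"], filter=first["filter"], info=extras,
        )
        bnd_records[first["id"]] = rec
        fmt_rows.extend(first["fmt"])

    # assemble in file order, symbolic and kept-BND interleaved
    out_records = []
    sym_iter = iter(records)
    for kind, rid in order:
        if kind == "sym":
            out_records.append(next(sym_iter))
        elif rid in bnd_records:
            out_records.append(bnd_records[rid])

    formats = pd.DataFrame(fmt_rows, columns=FORMAT_COLUMNS)
    kept = {rec.id for rec in out_records}
    formats = formats[formats["id"].isin(kept)]
    return build_container(out_records, header, formats=formats)


def _svtype_from_strands(s1: str, s2: str) -> str:
    return {("+", "-"): "DEL", ("-", "+"): "DUP", ("+", "+"): "INV", ("-", "-"): "INV"}[(s1, s2)]


def _ci(value) -> tuple[int, int]:
    if value is None:
        return 0, 0
    if isinstance(value, (list, tuple)):
        lo, hi = int(value[0]), int(value[1])
    else:
        lo = hi = int(value)
    return lo, hi


def _extras(info: dict) -> dict:
    out = {}
    for k, v in info.items():
        if k in _CONSUMED_INFO:
            continue
        out[k] = v
    return out


def _local_breakend(r, strand: str) -> Breakend:
    lo, hi = _ci(r["info"].get("CIPOS"))
    return Breakend(r["chrom"], r["pos"], strand, lo, hi)


def _symbolic_record(r, caller: str) -> SVRecord:
    info = r["info"]
    svtype = info.get("SVTYPE")
    if svtype not in ("DEL", "DUP", "INV", "INS", "BND"):
        raise SVTabError(f"record {r['id']}: unsupported SVTYPE {svtype!r}")
    chrom2 = info.get("CHR2", r["chrom"])
    chrom2 = chrom2[0] if isinstance(chrom2, list) else chrom2
    pos2 = info.get("POS2", info.get("END", r["stop"]))
    pos2 = int(pos2[0] if isinstance(pos2, list) else pos2)
    s1, s2 = _strands_for(caller, svtype, info, r["id"])
    lo1, hi1 = _ci(info.get("CIPOS"))
    lo2, hi2 = _ci(info.get("CIEND"))
    bp1 = Breakend(r["chrom"], r["pos"], s1, lo1, hi1)
    bp2 = Breakend(chrom2, pos2, s2, lo2, hi2)
    svlen = info.get("SVLEN")
    if svlen is not None:
        svlen = svlen[0] if isinstance(svlen, list) else svlen
        svlen = abs(int(svlen))
    elif r["chrom"] == chrom2 and svtype in ("DEL", "DUP", "INV"):
        svlen = abs(pos2 - r["pos"])
    return SVRecord(
        id=r["id"], bp1=bp1, bp2=bp2, svtype=svtype, svlen=svlen,
        qual=r["qual"], filter=r["filter"], info=_extras(info),
    )


# --------------------------------------------------------------------------- #
# VCF writing
# --------------------------------------------------------------------------- #

_CANONICAL_EXPORT = {
    "svtype": ("SVTYPE", "1", "String", "Type of structural variant"),
    "svlen": ("SVLEN", "1", "Integer", "Length of the structural variant"),
    "cipos": ("CIPOS", "2", "Integer", "Confidence interval around POS"),
    "ciend": ("CIEND", "2", "Integer", "Confidence interval around END"),
}


def _fmt_info_value(vals) -> str:
    return ",".join(str(v) for v in vals)


def write_vcf(container: SVContainer, path) -> None:
    """Write a container as VCF 4.2 in the caller-neutral dialect.

    BND events are re-expanded to bracket-notation mate pairs cross-linked
    by MATEID; all INFO tables and FORMAT values are exported with header
    declarations, so ``read_vcf(path, "generic")`` reproduces the
    container's positions, strands and INFO values.
    """
    header = container.header
    records = container.to_records()
    has_bnd = any(rec.bp2 is not None and rec.bp1.chrom != rec.bp2.chrom for rec in records) or any(
        rec.svtype == "BND" for rec in records
    )

    lines = ["##fileformat=VCFv4.2"]
    for name, length in header.contigs.items():
        if length:
            lines.append(f"##contig=<ID={name},length={length}>")
        else:
            lines.append(f"##contig=<ID={name}>")
    used_filters = set(container.filters["filter"]) if len(container.filters) else set()
    declared = dict(header.filters)
    for f in sorted(used_filters - set(declared) - {"PASS"}):
        declared[f] = "Filter"
    for fid, desc in declared.items():
        lines.append(f'##FILTER=<ID={fid},Description="{desc or "Filter"}">')

    info_decl = {}
    for key in container.infos:
        if key in _CANONICAL_EXPORT:
            vk, num, typ, desc = _CANONICAL_EXPORT[key]
            info_decl[vk] = (num, typ, desc)
        else:
            num, typ, desc = header.infos.get(key, (".", "String", ""))
            info_decl[key] = (num, typ, desc or f"svtab INFO {key}")
    info_decl["END"] = ("1", "Integer", "End position of the structural variant")
    if "STRANDS" not in info_decl:
        info_decl["STRANDS"] = ("1", "String", "Breakend strand orientation")
    if has_bnd:
        info_decl["MATEID"] = ("1", "String", "ID of mate breakend")
    for key, (num, typ, desc) in info_decl.items():
        lines.append(
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    fmt_keys = list(dict.fromkeys(container.formats["key"])) if len(container.formats) else []
    for key in fmt_keys:
        num, typ, desc = header.formats.get(key, ("1", "String", ""))
        if key == "GT":
            num, typ = "1", "String"
        lines.append(
            f'##FORMAT=<ID={key},Number={num},Type={typ},Description="{desc or key}">'
        )
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    samples = header.samples
    if samples and fmt_keys:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols))

    fmt_lookup: dict = {}
    if len(container.formats):
        for rid, sample, key, vi, val in container.formats.itertuples(index=False):
            fmt_lookup.setdefault(rid, {}).setdefault(sample, {}).setdefault(key, []).append(
                (vi, val)
            )

    for rec in records:
        extras = {
            k: v for k, v in rec.info.items()
        }
        qual = "." if rec.qual is None else (
            str(int(rec.qual)) if float(rec.qual).is_integer() else str(rec.qual)
        )
        filt = ";".join(rec.filter) if rec.filter else "."
        fmt_cells = ""
        if samples and fmt_keys:
            per = fmt_lookup.get(rec.id, {})
            keys_here = list(dict.fromkeys(
                k for s in samples for k in per.get(s, {})
            ))
            if "GT" in keys_here:
                keys_here = ["GT"] + [k for k in keys_here if k != "GT"]
            if not keys_here:
                keys_here = ["GT"]
            cells = []
            for s in samples:
                vals = []
                for k in keys_here:
                    pairs = sorted(per.get(s, {}).get(k, []))
                    vals.append(",".join(str(v) for _, v in pairs) if pairs else ".")
                cells.append(":".join(vals))
            fmt_cells = "\t" + ":".join(keys_here) + "\t" + "\t".join(cells)

        if rec.bp2 is None:
            info = _info_string(rec, extras, end=None, strands=None)
            alt = "N." if rec.bp1.strand == "+" else ".N"
            lines.append(
                f"{rec.bp1.chrom}\t{rec.bp1.pos}\t{rec.id}\tN\t{alt}\t{qual}\t{filt}\t{info}{fmt_cells}"
            )
            continue
        interchrom = rec.bp1.chrom != rec.bp2.chrom
        if rec.svtype == "BND" or interchrom:
            mate_id = f"{rec.id}_bnd2"
            ins = rec.info.get("insseq", "")
            ins = ins[0] if isinstance(ins, list) else (ins or "")
            alt1 = _bracket_alt("N", rec.bp2.chrom, rec.bp2.pos, rec.bp1.strand, rec.bp2.strand, ins)
            alt2 = _bracket_alt("N", rec.bp1.chrom, rec.bp1.pos, rec.bp2.strand, rec.bp1.strand, ins)
            info1 = _info_string(rec, extras, end=None, strands=None, bnd=True, mateid=mate_id, ci=rec.bp1)
            info2 = (
                f"SVTYPE=BND;MATEID={rec.id};CIPOS={rec.bp2.ci_lo},{rec.bp2.ci_hi}"
            )
            lines.append(
                f"{rec.bp1.chrom}\t{rec.bp1.pos}\t{rec.id}\tN\t{alt1}\t{qual}\t{filt}\t{info1}{fmt_cells}"
            )
            empty_fmt = ""
            if samples and fmt_keys:
                empty_fmt = "\tGT" + "\t./." * len(samples)
            lines.append(
                f"{rec.bp2.chrom}\t{rec.bp2.pos}\t{mate_id}\tN\t{alt2}\t{qual}\t{filt}\t{info2}{empty_fmt}"
            )
        else:
            info = _info_string(rec, extras, end=rec.bp2.pos, strands=rec.bp1.strand + rec.bp2.strand)
            lines.append(
                f"{rec.bp1.chrom}\t{rec.bp1.pos}\t{rec.id}\tN\t<{rec.svtype}>\t{qual}\t{filt}\t{info}{fmt_cells}"
            )

    Path(path).write_text("\n".join(lines) + "\n")


def _bracket_alt(ref: str, mate_chrom: str, mate_pos: int, s_local: str, s_mate: str, ins: str) -> str:
    loc = f"{mate_chrom}:{mate_pos}"
    if s_local == "+" and s_mate == "-":
        return f"{ref}{ins}[{loc}["
    if s_local == "+" and s_mate == "+":
        return f"{ref}{ins}]{loc}]"
    if s_local == "-" and s_mate == "+":
        return f"]{loc}]{ins}{ref}"
    return f"[{loc}[{ins}{ref}"


def _info_string(rec, extras, end, strands, bnd=False, mateid=None, ci=None) -> str:
    parts = [f"SVTYPE={'BND' if bnd else rec.svtype}"]
    if bnd:
        parts.append(f"MATEID={mateid}")
    if end is not None:
        parts.append(f"END={end}")
    if rec.svlen is not None and not bnd:
        parts.append(f"SVLEN={rec.svlen}")
    b1 = ci if ci is not None else rec.bp1
    parts.append(f"CIPOS={b1.ci_lo},{b1.ci_hi}")
    if not bnd and rec.bp2 is not None:
        parts.append(f"CIEND={rec.bp2.ci_lo},{rec.bp2.ci_hi}")
    if strands is not None and "STRANDS" not in extras:
        parts.append(f"STRANDS={strands}")
    for key, val in extras.items():
        if key == "insseq" and bnd:
            continue  # carried in the ALT bracket notation
        vals = val if isinstance(val, (list, tuple)) else [val]
        if len(vals) == 1 and vals[0] is True:
            parts.append(key)
        else:
            parts.append(f"{key}={_fmt_info_value(vals)}")
    return ";".join(parts)


# --------------------------------------------------------------------------- #
# BEDPE
# --------------------------------------------------------------------------- #

_BEDPE_STD = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def read_bedpe(path) -> SVContainer:
    """Read a 10+ column BEDPE file into a container.

    The 1-based breakpoint position is taken as the interval end (so a
    point breakend is the conventional ``[pos-1, pos)`` interval); wider
    intervals become the CIPOS/CIEND confidence interval unless explicit
    ``cipos``/``ciend`` columns are present. SV type is taken from an
    ``svtype`` column when available and otherwise derived from the strand
    pair (+- DEL, -+ DUP, ++/-- INV, interchromosomal BND).
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise SVTabError(f"{path}: empty BEDPE file")
    first = lines[0]
    names = None
    if first.startswith("#"):
        names = first.lstrip("#").split("\t")
        body = lines[1:]
    else:
        fields = first.split("\t")
        if len(fields) >= 2 and not _is_int(fields[1]):
            names = fields
            body = lines[1:]
        else:
            body = lines
    if body:
        ncol = len(body[0].split("\t"))
    else:
        ncol = len(names) if names else 10
    if ncol < 10:
        raise SVTabError(f"{path}: BEDPE needs >= 10 columns, found {ncol}")
    if names is None:
        names = _BEDPE_STD + [f"col{i + 1}" for i in range(10, ncol)]
    extra_names = names[10:]

    records = []
    for lineno, ln in enumerate(body, start=2 if names is not None and len(body) < len(lines) else 1):
        fields = ln.split("\t")
        if len(fields) < 10:
            raise SVTabError(f"{path} line {lineno}: fewer than 10 columns")
        (c1, s1, e1, c2, s2, e2, name, score, st1, st2) = fields[:10]
        for st in (st1, st2):
            if st not in ("+", "-", "."):
                raise SVTabError(f"{path} line {lineno}: invalid strand {st!r}")
        s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
        extras = dict(zip(extra_names, fields[10:]))
        st1 = "+" if st1 == "." else st1
        st2 = "-" if st2 == "." else st2
        pos1, pos2 = e1, e2
        ci1 = _parse_ci_col(extras.pop("cipos", None)) or (s1 + 1 - e1, 0)
        single = c2 in (".", "")
        ci2 = _parse_ci_col(extras.pop("ciend", None)) or ((s2 + 1 - e2, 0) if not single else (0, 0))
        svtype = extras.pop("svtype", None)
        if svtype is None:
            if single:
                svtype = "BND"
            elif c1 != c2:
                svtype = "BND"
            else:
                svtype = _svtype_from_strands(st1, st2)
        svlen = extras.pop("svlen", None)
        if svlen is not None and svlen != ".":
            svlen = abs(int(float(svlen)))
        elif not single and c1 == c2 and svtype in ("DEL", "DUP", "INV"):
            svlen = abs(pos2 - pos1)
        else:
            svlen = None
        filt = extras.pop("filter", None)
        filters = [] if filt in (None, ".", "") else filt.split(";")
        info = {}
        for k, v in extras.items():
            if v in (".", ""):
                continue
            vals = [_coerce(x) for x in str(v).split(",")]
            info[k] = vals if len(vals) > 1 else vals[0]
        qual = None if score in (".", "") else float(score)
        rid = name if name not in (".", "") else f"sv_{lineno}"
        bp1 = Breakend(c1, pos1, st1, *_order_ci(ci1))
        bp2 = None if single else Breakend(c2, pos2, st2, *_order_ci(ci2))
        records.append(
            SVRecord(id=rid, bp1=bp1, bp2=bp2, svtype=svtype,
                     svlen=svlen if not single and c1 == c2 else None,
                     qual=qual, filter=filters, info=info)
        )
    header = VCFHeader()
    for rec in records:
        header.contigs.setdefault(rec.bp1.chrom, None)
        if rec.bp2 is not None:
            header.contigs.setdefault(rec.bp2.chrom, None)
    return build_container(records, header)


def _order_ci(ci):
    lo, hi = ci
    return (lo, hi) if lo <= hi else (hi, lo)


def _parse_ci_col(val):
    if val in (None, ".", ""):
        return None
    parts = str(val).split(",")
    return int(parts[0]), int(parts[1])


def _is_int(x) -> bool:
    try:
        int(x)
        return True
    except (TypeError, ValueError):
        return False


def _coerce(x: str):
    for conv in (int, float):
        try:
            return conv(x)
        except ValueError:
            continue
    return x


def write_bedpe(container: SVContainer, path) -> None:
    """Write a container as headered BEDPE (0-based half-open intervals).

    Breakpoints become point intervals ``[pos-1, pos)``; confidence
    intervals, SV type/length, FILTER strings and all other INFO tables are
    exported as named trailing columns, making
    ``read_bedpe(write_bedpe(c))`` lossless for positions, strands and
    INFO values.
    """
    records = container.to_records()
    canonical = ["svtype", "svlen", "cipos", "ciend", "filter"]
    extra_keys = [k for k in container.infos if k not in ("svtype", "svlen", "cipos", "ciend")]
    names = _BEDPE_STD + canonical + extra_keys
    rows = ["#" + "\t".join(names)]
    for rec in records:
        b1, b2 = rec.bp1, rec.bp2
        qual = "." if rec.qual is None else (
            str(int(rec.qual)) if float(rec.qual).is_integer() else str(rec.qual)
        )
        cells = [
            b1.chrom, str(b1.pos - 1), str(b1.pos),
            b2.chrom if b2 else ".", str(b2.pos - 1) if b2 else ".",
            str(b2.pos) if b2 else ".",
            rec.id, qual, b1.strand, b2.strand if b2 else ".",
            rec.svtype,
            str(rec.svlen) if rec.svlen is not None else ".",
            f"{b1.ci_lo},{b1.ci_hi}",
            f"{b2.ci_lo},{b2.ci_hi}" if b2 else ".",
            ";".join(rec.filter) if rec.filter else ".",
        ]
        for k in extra_keys:
            if k in rec.info:
                v = rec.info[k]
                vals = v if isinstance(v, (list, tuple)) else [v]
                cells.append(",".join(str(x) for x in vals))
            else:
                cells.append(".")
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")
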