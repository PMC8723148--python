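"""Synthetic data generators: toy references, caller VCFs, count matrices.

Everything the test suite and the examples consume is generated here, with
seeded randomness and no external downloads.

``simulate_caller_vcfs`` reproduces the multi-caller merge study design:
four VCF files mimicking Manta, Delly, Lumpy and Gridss output dialects
that share a set of truth events recorded with positional scatter bounded
by ``jitter`` bp (so any two callers' positions for the same event differ
by at most ``jitter``), with CIPOS/CIEND wide enough that the confidence
intervals of shared breakends always overlap pairwise. Each file also
carries caller-private events, so support-based filtering has something to
remove. A truth table maps every emitted record id to its truth event.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import FeatureMatrix
from .datamodel import SVTabError

__all__ = [
    "make_toy_reference",
    "simulate_caller_vcfs",
    "simulate_signature_matrix",
    "make_true_signatures",
]


def make_toy_reference(n_chroms: int, length: int, seed: int, out_path) -> Path:
    """Write a FASTA of ``n_chroms`` uniform-random ACGT chromosomes.

    Chromosomes are named chr1..chrN; output is deterministic per seed.
    """
    if length < 1:
        raise SVTabError(f"chromosome length must be >= 1, got {length}")
    if n_chroms < 1:
        raise SVTabError(f"n_chroms must be >= 1, got {n_chroms}")
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    with out_path.open("w") as fh:
        for c in range(1, n_chroms + 1):
            fh.write(f">chr{c}\n")
            seq = "".join(rng.choice(list("ACGT"), size=length))
            for i in range(0, length, 60):
                fh.write(seq[i:i + 60] + "\n")
    return out_path


# --------------------------------------------------------------------------- #
# four-caller VCF simulation
# --------------------------------------------------------------------------- #

_CALLER_ORDER = ("manta", "delly", "lumpy", "gridss")
_TYPE_CYCLE = ("DEL", "DUP", "INV", "BND")
_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+"), "BND": ("+", "-")}
_CT = {("+", "-"): "3to5", ("-", "+"): "5to3", ("+", "+"): "3to3", ("-", "-"): "5to5"}

_EVENT_SPACING = 50_000  # truth events far enough apart never to co-cluster
_PRIVATE_FRACTION = 0.2


def _bracket(mate_chrom, mate_pos, s_local, s_mate):
    loc = f"{mate_chrom}:{mate_pos}"
    if (s_local, s_mate) == ("+", "-"):
        return f"N[{loc}["
    if (s_local, s_mate) == ("+", "+"):
        return f"N]{loc}]"
    if (s_local, s_mate) == ("-", "+"):
        return f"]{loc}]N"
    return f"[{loc}[N"


def _vcf_header(contigs: dict, extra_info: list) -> list:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    base = [
        ('SVTYPE', '1', 'String', 'Type of structural variant'),
        ('END', '1', 'Integer', 'End position'),
        ('SVLEN', '1', 'Integer', 'SV length'),
        ('CIPOS', '2', 'Integer', 'Confidence interval around POS'),
        ('CIEND', '2', 'Integer', 'Confidence interval around END'),
        ('MATEID', '1', 'String', 'ID of mate breakend'),
    ]
    for key, num, typ, desc in base + extra_info:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=SU,Number=1,Type=Integer,Description="Supporting reads">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1")
    return lines


def simulate_caller_vcfs(truth_n: int, jitter: int, seed: int, out_dir):
    """Emit four caller-dialect VCFs sharing jittered truth events.

    Returns ``(paths, truth)`` where ``paths`` maps caller name to VCF
    path and ``truth`` is a DataFrame with one row per emitted record:
    (caller, record_id, truth_id, shared). Every truth event is emitted by
    all four callers; each caller additionally emits private events
    (20% of ``truth_n``, at least one) that no other caller reports.

    Pairwise positional scatter of a shared event across callers is at
    most ``jitter`` bp, and emitted CIPOS/CIEND intervals of width
    ``2 * jitter`` guarantee that shared breakends' confidence intervals
    always overlap, so proximity merging at ``jitter`` bp and
    confidence-interval merging both recover the truth clustering.
    """
    if truth_n < 1:
        raise SVTabError(f"truth_n must be >= 1, got {truth_n}")
    if jitter < 0:
        raise SVTabError(f"jitter must be >= 0, got {jitter}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = ["chr1", "chr2", "chr3"]
    events = []
    for e in range(truth_n):
        svtype = _TYPE_CYCLE[e % len(_TYPE_CYCLE)]
        chrom1 = chroms[e % 3]
        pos1 = 50_000 + (e // 3) * _EVENT_SPACING
        if svtype == "BND":
            chrom2 = chroms[(e + 1) % 3]
            pos2 = 2_000_000 + (e // 3) * _EVENT_SPACING
        else:
            chrom2 = chrom1
            pos2 = pos1 + int(rng.integers(5_000, 20_000))
        events.append(
            dict(truth_id=f"truth_{e}", svtype=svtype, chrom1=chrom1, pos1=pos1,
                 chrom2=chrom2, pos2=pos2, strands=_STRANDS[svtype])
        )

    n_private = max(1, math.ceil(_PRIVATE_FRACTION * truth_n))
    private: dict[str, list] = {}
    for ci, caller in enumerate(_CALLER_ORDER):
        zone = 5_000_000 + ci * 1_000_000
        evs = []
        for j in range(n_private):
            pos1 = zone + j * _EVENT_SPACING
            pos2 = pos1 + int(rng.integers(5_000, 20_000))
            evs.append(
                dict(truth_id=f"private_{caller}_{j}", svtype="DEL", chrom1="chr1",
                     pos1=pos1, chrom2="chr1", pos2=pos2, strands=("+", "-"))
            )
        private[caller] = evs

    max_pos = max(
        [ev["pos2"] for ev in events] + [ev["pos1"] for ev in events]
        + [ev["pos2"] for evs in private.values() for ev in evs]
    )
    contigs = {c: max_pos + 100_000 for c in chroms}

    half = jitter // 2
    ci_lo, ci_hi = -jitter, jitter
    truth_rows = []
    paths = {}

    for caller in _CALLER_ORDER:
        lines = _vcf_header(
            contigs,
            extra_info=[
                ("CHR2", "1", "String", "Second chromosome"),
                ("CT", "1", "String", "Paired-end signature orientation"),
                ("STRANDS", ".", "String", "Strand orientation and support"),
                ("SECONDARY", "0", "Flag", "Secondary breakend record"),
                ("INV3", "0", "Flag", "Inversion of 3' junction"),
                ("INV5", "0", "Flag", "Inversion of 5' junction"),
            ],
        )
        all_events = [(ev, True) for ev in events] + [(ev, False) for ev in private[caller]]
        for idx, (ev, shared) in enumerate(all_events):
            d1 = int(rng.integers(-half, half + 1)) if half else 0
            d2 = int(rng.integers(-half, half + 1)) if half else 0
            p1, p2 = ev["pos1"] + d1, ev["pos2"] + d2
            s1, s2 = ev["strands"]
            qual = int(rng.integers(100, 1000))
            su = int(rng.integers(3, 30))
            fmt = f"GT:SU\t0/1:{su}"
            ci = f"CIPOS={ci_lo},{ci_hi};CIEND={ci_lo},{ci_hi}"
            svtype = ev["svtype"]
            ids = _emit(
                caller, lines, idx, svtype, ev["chrom1"], p1, ev["chrom2"], p2,
                s1, s2, qual, ci, fmt,
            )
            for rid in ids:
                truth_rows.append((caller, rid, ev["truth_id"], shared))
        path = out_dir / f"{caller}.vcf"
        path.write_text("\n".join(lines) + "\n")
        paths[caller] = path

    truth = pd.DataFrame(truth_rows, columns=["caller", "record_id", "truth_id", "shared"])
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return paths, truth


def _emit(caller, lines, idx, svtype, c1, p1, c2, p2, s1, s2, qual, ci, fmt):
    """Append one event in the caller's dialect; return emitted record ids."""
    if caller == "gridss" or svtype == "BND":
        if caller == "manta":
            id1, id2 = f"MantaBND:{idx}:0", f"MantaBND:{idx}:1"
        elif caller == "delly":
            # Delly writes translocations as a single record with CHR2/CT
            rid = f"BND{idx:05d}"
            lines.append(
                f"{c1}\t{p1}\t{rid}\tN\t<BND>\t{qual}\tPASS\t"
                f"SVTYPE=BND;CHR2={c2};END={p2};CT={_CT[(s1, s2)]};{ci}\t{fmt}"
            )
            return [rid]
        elif caller == "lumpy":
            id1, id2 = f"{idx}_1", f"{idx}_2"
        else:
            id1, id2 = f"gridss{idx}o", f"gridss{idx}h"
        alt1 = _bracket(c2, p2, s1, s2)
        alt2 = _bracket(c1, p1, s2, s1)
        extra1 = extra2 = ""
        if caller == "lumpy":
            extra1 = f";STRANDS={s1}{s2}:{6}"
            extra2 = f";STRANDS={s2}{s1}:{6};SECONDARY"
        cipos_only = ci.split(";")[0]
        lines.append(
            f"{c1}\t{p1}\t{id1}\tN\t{alt1}\t{qual}\tPASS\t"
            f"SVTYPE=BND;MATEID={id2};{cipos_only}{extra1}\t{fmt}"
        )
        lines.append(
            f"{c2}\t{p2}\t{id2}\tN\t{alt2}\t{qual}\tPASS\t"
            f"SVTYPE=BND;MATEID={id1};{cipos_only}{extra2}\t{fmt}"
        )
        return [id1, id2]

    svlen = p2 - p1
    if caller == "manta":
        rid = f"Manta{svtype}:{idx}"
        info = f"SVTYPE={svtype};END={p2};SVLEN={-svlen if svtype == 'DEL' else svlen};{ci}"
        if svtype == "INV":
            info += ";INV3" if (s1, s2) == ("+", "+") else ";INV5"
    elif caller == "delly":
        rid = f"{svtype}{idx:05d}"
        info = f"SVTYPE={svtype};CHR2={c2};END={p2};CT={_CT[(s1, s2)]};{ci}"
    elif caller == "lumpy":
        rid = str(idx)
        info = (
            f"SVTYPE={svtype};END={p2};SVLEN={-svlen if svtype == 'DEL' else svlen};"
            f"STRANDS={s1}{s2}:{7};{ci}"
        )
    else:  # pragma: no cover - gridss handled above
        raise AssertionError
    lines.append(f"{c1}\t{p1}\t{rid}\tN\t<{svtype}>\t{qual}\tPASS\t{info}\t{fmt}")
    return [rid]


# --------------------------------------------------------------------------- #
# signature-matrix simulation
# --------------------------------------------------------------------------- #

def make_true_signatures(n_classes: int, k: int, seed: int) -> pd.DataFrame:
    """Column-stochastic classes x k signature matrix with distinct supports.

    Each signature concentrates ~90% of its mass on its own block of
    classes with a small uniform background, so different signatures are
    mutually well separated (low pairwise cosine similarity) — the regime
    where recovery is well posed.
    """
    if k > n_classes:
        raise SVTabError("need at least one class per signature")
    rng = np.random.default_rng(seed)
    sig = np.full((n_classes, k), 0.1 / n_classes)
    blocks = np.array_split(np.arange(n_classes), k)
    for j, block in enumerate(blocks):
        weights = rng.dirichlet(np.ones(len(block)))
        sig[block, j] += 0.9 * weights
    sig /= sig.sum(axis=0, keepdims=True)
    return pd.DataFrame(sig, index=[f"class_{i + 1}" for i in range(n_classes)],
                        columns=[f"true_{j + 1}" for j in range(k)])


def simulate_signature_matrix(
    n_samples: int,
    true_signatures: pd.DataFrame,
    exposure_scale: float,
    seed: int,
):
    """Draw a Poisson count matrix from known signatures and exposures.

    Exposures are gamma(shape=2, scale=``exposure_scale``) per signature
    and sample; counts are Poisson around ``S @ E``. Returns
    ``(FeatureMatrix, truth)`` with ``truth`` holding the generating
    signatures and exposures.
    """
    S = np.asarray(true_signatures, dtype=float)
    if (S < 0).any() or not np.allclose(S.sum(axis=0), 1.0, atol=1e-8):
        raise SVTabError("true_signatures must be column-stochastic")
    if exposure_scale < 0:
        raise SVTabError("exposure_scale must be >= 0")
    rng = np.random.default_rng(seed)
    k = S.shape[1]
    exposures = rng.gamma(shape=2.0, scale=exposure_scale, size=(k, n_samples)) if exposure_scale > 0 else np.zeros((k, n_samples))
    counts = rng.poisson(S @ exposures).T  # samples x classes
    classes = (
        list(true_signatures.index)
        if isinstance(true_signatures, pd.DataFrame)
        else [f"class_{i + 1}" for i in range(S.shape[0])]
    )
    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    fm = FeatureMatrix(
        values=pd.DataFrame(counts, index=samples, columns=classes),
        sample_order=samples,
        class_order=classes,
    )
    truth = {
        "signatures": pd.DataFrame(S, index=classes, columns=[f"true_{j + 1}" for j in range(k)]),
        "exposures": pd.DataFrame(exposures, columns=samples,
                                  index=[f"true_{j + 1}" for j in range(k)]),
    }
    return fm, truth
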