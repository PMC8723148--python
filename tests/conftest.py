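import numpy as np
import pytest

from svtab.datamodel import Breakend, SVRecord, VCFHeader, build_container


def make_del(rid, chrom="chr1", pos1=1000, pos2=6000, ci=(0, 0), **kw):
    return SVRecord(
        id=rid,
        bp1=Breakend(chrom, pos1, "+", *ci),
        bp2=Breakend(chrom, pos2, "-", *ci),
        svtype="DEL",
        **kw,
    )


@pytest.fixture
def header():
    return VCFHeader(contigs={"chr1": 1_000_000, "chr2": 1_000_000}, samples=["s1"])


@pytest.fixture
def small_container(header):
    recs = [
        make_del("sv1", pos1=1000, pos2=6000, qual=50.0),
        make_del("sv2", pos1=20_000, pos2=80_000, qual=10.0, filter=["LowQual"]),
        SVRecord(
            id="sv3",
            bp1=Breakend("chr1", 40_000, "-"),
            bp2=Breakend("chr1", 140_000, "+"),
            svtype="DUP",
        ),
        SVRecord(
            id="sv4",
            bp1=Breakend("chr1", 500_000, "+"),
            bp2=Breakend("chr2", 700, "-"),
            svtype="BND",
        ),
    ]
    return build_container(recs, header)


@pytest.fixture(scope="session")
def sim_vcfs(tmp_path_factory):
    """Four jittered caller-dialect VCFs sharing 20 truth events."""
    from svtab.simulate import simulate_caller_vcfs

    out = tmp_path_factory.mktemp("sim")
    paths, truth = simulate_caller_vcfs(truth_n=20, jitter=100, seed=3, out_dir=out)
    return paths, truth


@pytest.fixture(scope="session")
def sim_containers(sim_vcfs):
    from svtab.io import read_vcf

    paths, truth = sim_vcfs
    return {caller: read_vcf(path, caller) for caller, path in paths.items()}, truth


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    from svtab.microhomology import ReferenceGenome
    from svtab.simulate import make_toy_reference

    path = make_toy_reference(1, 10_000, seed=42, out_path=tmp_path_factory.mktemp("ref") / "toy.fa")
    return ReferenceGenome(path)


def random_breakend_records(rng: np.random.Generator, n: int, chroms=("chr1", "chr2")):
    """Random two-breakend records for oracle-equivalence tests."""
    recs = []
    for i in range(n):
        svtype = rng.choice(["DEL", "DUP", "INV", "BND", "INS"])
        c1 = str(rng.choice(chroms))
        p1 = int(rng.integers(1_000, 200_000))
        ci = (-int(rng.integers(0, 150)), int(rng.integers(0, 150)))
        if svtype == "BND":
            c2 = str(rng.choice([c for c in chroms if c != c1]))
            p2 = int(rng.integers(1_000, 200_000))
            s1, s2 = rng.choice(["+", "-"]), rng.choice(["+", "-"])
        else:
            c2 = c1
            p2 = p1 + int(rng.integers(60, 30_000))
            s1, s2 = {"DEL": "+-", "DUP": "-+", "INS": "+-", "INV": "++"}[svtype]
        svlen = int(rng.integers(60, 500)) if svtype == "INS" else None
        recs.append(
            SVRecord(
                id=f"r{i}",
                bp1=Breakend(c1, p1, str(s1), *ci),
                bp2=Breakend(c2, p2, str(s2), *ci),
                svtype=str(svtype),
                svlen=svlen,
            )
        )
    return recs
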