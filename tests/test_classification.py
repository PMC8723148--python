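import numpy as np
import pytest

from svtab.annotation import build_interval_index
from svtab.classification import (
    ClassDefinition,
    classify,
    feature_matrix,
    get_default_definitions,
)
from svtab.datamodel import (
    Breakend,
    MultiSVContainer,
    SVRecord,
    SVTabError,
    build_container,
)

from conftest import make_del


@pytest.fixture
def cfs_bed(tmp_path):
    return build_interval_index(
        _write(tmp_path, "cfs.bed", [("chr1", 0, 10_000, "FRA1A")])
    )


@pytest.fixture
def timing_bed(tmp_path):
    rows = [("chr1", 0, 250_000, "early"), ("chr1", 250_000, 1_000_000, "late")]
    return build_interval_index(_write(tmp_path, "timing.bed", rows))


def _write(tmp_path, name, rows):
    p = tmp_path / name
    p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return p


class TestClassify:
    def test_first_match_wins_and_fallback(self, small_container):
        defn = ClassDefinition(
            rules=[
                ("any_del", ["svtype == DEL"]),
                ("small", ["svlen < 50000"]),  # sv1 also matches this, but later
            ]
        )
        out = classify(small_container, defn)
        labels = {k: v[0] for k, v in out.info_dict("manual_sv_type").items()}
        assert labels == {
            "sv1": "any_del",
            "sv2": "any_del",
            "sv3": "others",
            "sv4": "others",
        }

    def test_or_of_conjunctions(self, small_container):
        c = small_container.add_info("cfs1", {"sv1": True, "sv2": False, "sv3": False, "sv4": False})
        c = c.add_info("cfs2", {"sv1": False, "sv2": False, "sv3": True, "sv4": False})
        defn = ClassDefinition(
            rules=[("CFS_SV", [["cfs1 == True"], ["cfs2 == True"]])]
        )
        labels = {k: v[0] for k, v in classify(c, defn).info_dict("manual_sv_type").items()}
        assert labels["sv1"] == "CFS_SV" and labels["sv3"] == "CFS_SV"
        assert labels["sv2"] == "others"

    def test_missing_info_names_key(self, small_container):
        defn = ClassDefinition(rules=[("x", ["absent_key == 1"])])
        with pytest.raises(SVTabError, match="absent_key"):
            classify(small_container, defn)

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(SVTabError):
            ClassDefinition(rules=[("a", ["svtype == DEL"]), ("a", ["svtype == DUP"])])

    def test_partition_property(self, sim_containers):
        containers, _ = sim_containers
        defn = get_default_definitions("simple")
        for c in containers.values():
            labels = classify(c, defn).info_dict("manual_sv_type")
            assert set(labels) == set(c.ids)
            assert all(len(v) == 1 for v in labels.values())

    def test_determinism(self, small_container):
        defn = get_default_definitions("simple")
        a = classify(small_container, defn).info_dict("manual_sv_type")
        b = classify(small_container, defn).info_dict("manual_sv_type")
        assert a == b

    def test_labels_survive_vcf_round_trip(self, small_container, tmp_path):
        from svtab.io import read_vcf, write_vcf

        defn = get_default_definitions("simple")
        out = classify(small_container, defn)
        path = tmp_path / "classified.vcf"
        write_vcf(out, path)
        back = read_vcf(path, "generic")
        assert back.info_dict("manual_sv_type") == out.info_dict("manual_sv_type")


class TestDefaultSchemes:
    def test_simple_has_16_classes(self):
        defn = get_default_definitions("simple")
        assert len(defn.class_names) == 16
        assert defn.class_names[-1] == "translocation"
        assert "DEL_<1kb" in defn.class_names

    def test_simple_length_bins(self):
        recs = [
            make_del("a", pos1=1000, pos2=1500),  # 500 bp
            make_del("b", pos1=1000, pos2=6000),  # 5 kb
            make_del("c", pos1=1000, pos2=2_001_000),  # 2 Mb
            SVRecord(id="t", bp1=Breakend("chr1", 100, "+"),
                     bp2=Breakend("chr2", 100, "-"), svtype="BND"),
        ]
        labels = classify(build_container(recs), get_default_definitions("simple"))
        got = {k: v[0] for k, v in labels.info_dict("manual_sv_type").items()}
        assert got == {
            "a": "DEL_<1kb",
            "b": "DEL_1kb-10kb",
            "c": "DEL_>1Mb",
            "t": "translocation",
        }

    def test_pcawg_like_has_25_classes(self, cfs_bed, timing_bed):
        defn = get_default_definitions("pcawg_like", cfs_bed, timing_bed)
        assert len(defn.class_names) == 25
        assert defn.class_names[0] == "CFS_SV"
        assert defn.class_names[-1] == "others"

    def test_pcawg_like_requires_both_indices(self, cfs_bed):
        with pytest.raises(SVTabError, match="timing"):
            get_default_definitions("pcawg_like", cfs_bed, None)

    def test_pcawg_like_classification(self, cfs_bed, timing_bed):
        recs = [
            make_del("in_cfs", pos1=5_000, pos2=80_000),  # bp1 in the CFS
            make_del("early_small", pos1=100_000, pos2=130_000),  # early, <50 kb
            make_del("late_medium", pos1=300_000, pos2=400_000),  # late, 50-500 kb
        ]
        defn = get_default_definitions("pcawg_like", cfs_bed, timing_bed)
        labels = classify(build_container(recs), defn)
        got = {k: v[0] for k, v in labels.info_dict("manual_sv_type").items()}
        assert got == {
            "in_cfs": "CFS_SV",
            "early_small": "DEL_early_small",
            "late_medium": "DEL_late_medium",
        }

    def test_unknown_scheme(self):
        with pytest.raises(SVTabError):
            get_default_definitions("fancy")


class TestFeatureMatrix:
    def test_counts_and_zero_fill(self):
        a = build_container([make_del("x", pos1=1000, pos2=1500)])
        b = build_container(
            [SVRecord(id="t", bp1=Breakend("chr1", 100, "+"),
                      bp2=Breakend("chr2", 100, "-"), svtype="BND")]
        )
        fm = feature_matrix(
            MultiSVContainer({"A": a, "B": b}), get_default_definitions("simple")
        )
        assert fm.values.shape == (2, 16)
        assert fm.values.loc["A", "DEL_<1kb"] == 1
        assert fm.values.loc["B", "DEL_<1kb"] == 0
        assert fm.values.loc["B", "translocation"] == 1

    def test_row_sums_equal_record_counts(self, sim_containers):
        containers, _ = sim_containers
        fm = feature_matrix(
            MultiSVContainer(containers), get_default_definitions("simple")
        )
        for caller, c in containers.items():
            assert fm.values.loc[caller].sum() == len(c)

    def test_pcawg_matrix_has_25_columns(self, sim_containers, cfs_bed, timing_bed):
        containers, _ = sim_containers
        defn = get_default_definitions("pcawg_like", cfs_bed, timing_bed)
        fm = feature_matrix(MultiSVContainer(containers), defn)
        assert fm.values.shape[1] == 25

    def test_empty_collection_rejected(self):
        with pytest.raises(SVTabError):
            feature_matrix(MultiSVContainer(), get_default_definitions("simple"))

    def test_tsv_round_trip(self, tmp_path, sim_containers):
        from svtab.classification import FeatureMatrix

        containers, _ = sim_containers
        fm = feature_matrix(
            MultiSVContainer(containers), get_default_definitions("simple")
        )
        path = tmp_path / "fm.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.read_tsv(path)
        assert back.values.equals(fm.values)


def test_timing_conflict_classified_unknown(tmp_path):
    """A breakend overlapping early AND late zones gets 'unknown' timing."""
    timing = build_interval_index(
        _write(tmp_path, "t.bed", [("chr1", 0, 500_000, "early"), ("chr1", 100_000, 500_000, "late")])
    )
    cfs = build_interval_index(_write(tmp_path, "c.bed", [("chr2", 0, 10, "FRA")]))
    recs = [make_del("conflicted", pos1=200_000, pos2=230_000)]
    defn = get_default_definitions("pcawg_like", cfs, timing)
    labels = classify(build_container(recs), defn)
    assert labels.info_dict("manual_sv_type")["conflicted"] == ["DEL_unknown_timing"]
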