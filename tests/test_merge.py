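import itertools

import networkx as nx
import numpy as np
import pytest

from svtab.datamodel import Breakend, SVRecord, SVTabError, build_container
from svtab.merge import filter_by_support, merge_containers

from conftest import random_breakend_records


def _container(recs):
    return build_container(recs)


def _del(rid, p1, p2, strands=("+", "-"), ci=(0, 0), svtype=None):
    svtype = svtype or {"+-": "DEL", "-+": "DUP", "++": "INV", "--": "INV"}["".join(strands)]
    return SVRecord(
        id=rid,
        bp1=Breakend("chr1", p1, strands[0], *ci),
        bp2=Breakend("chr1", p2, strands[1], *ci),
        svtype=svtype,
    )


# ---------------------------------------------------------------------- #
# independent oracle: O(n^2) pairwise predicate + connected components
# ---------------------------------------------------------------------- #

def oracle_clusters(containers, mode, threshold):
    items = []
    for caller, c in containers.items():
        for rec in c.to_records():
            if rec.bp2 is not None:
                items.append((caller, rec))
    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    for i, j in itertools.combinations(range(len(items)), 2):
        a, b = items[i][1], items[j][1]
        if (a.bp1.chrom, a.bp2.chrom) != (b.bp1.chrom, b.bp2.chrom):
            continue
        if a.bp1.strand != b.bp1.strand or a.bp2.strand != b.bp2.strand:
            continue
        if mode == "proximity":
            if abs(a.bp1.pos - b.bp1.pos) > threshold or abs(a.bp2.pos - b.bp2.pos) > threshold:
                continue
        else:
            if max(a.bp1.pos + a.bp1.ci_lo, b.bp1.pos + b.bp1.ci_lo) > min(
                a.bp1.pos + a.bp1.ci_hi, b.bp1.pos + b.bp1.ci_hi
            ):
                continue
            if max(a.bp2.pos + a.bp2.ci_lo, b.bp2.pos + b.bp2.ci_lo) > min(
                a.bp2.pos + a.bp2.ci_hi, b.bp2.pos + b.bp2.ci_hi
            ):
                continue
        if a.bp1.chrom == a.bp2.chrom:
            def span(r):
                if r.svtype == "INS":
                    return r.bp1.pos, r.bp1.pos + max(r.svlen or 1, 1)
                return r.bp1.pos, r.bp2.pos

            lo_a, hi_a = span(a)
            lo_b, hi_b = span(b)
            if max(lo_a, lo_b) > min(hi_a, hi_b):
                continue
        g.add_edge(i, j)
    partition = {}
    for cid, comp in enumerate(nx.connected_components(g)):
        for i in comp:
            caller, rec = items[i]
            partition[(caller, rec.id)] = cid
    return partition


def _same_partition(a: dict, b: dict) -> bool:
    assert set(a) == set(b)
    keys = list(a)
    remap: dict = {}
    for k in keys:
        if a[k] in remap:
            if remap[a[k]] != b[k]:
                return False
        else:
            remap[a[k]] = b[k]
    return len(set(remap.values())) == len(remap)


class TestMergeConditions:
    def test_nearby_concordant_overlapping_dels_merge(self):
        inputs = {
            "c1": _container([_del("x", 1000, 5000)]),
            "c2": _container([_del("y", 1050, 5040)]),
        }
        res = merge_containers(inputs, "proximity", 100)
        labels = res.cluster_labels()
        assert labels[("c1", "x")] == labels[("c2", "y")]
        assert res.container.info_dict("supportingcallercount") == {"merged_0": [2]}

    def test_discordant_strands_do_not_merge(self):
        inputs = {
            "c1": _container([_del("x", 1000, 5000, strands=("+", "-"))]),
            "c2": _container([_del("y", 1000, 5000, strands=("-", "+"))]),
        }
        res = merge_containers(inputs, "proximity", 100)
        assert res.membership["mergedid"].nunique() == 2

    def test_non_overlapping_spans_do_not_merge(self):
        inputs = {
            "c1": _container([_del("x", 1000, 1040)]),
            "c2": _container([_del("y", 1090, 1130)]),
        }
        res = merge_containers(inputs, "proximity", 100)
        assert res.membership["mergedid"].nunique() == 2

    def test_input_validation(self, small_container):
        with pytest.raises(SVTabError):
            merge_containers({"only": small_container})
        with pytest.raises(SVTabError):
            merge_containers(
                {"a": small_container, "b": small_container}, "proximity", -1
            )


class TestFilterBySupport:
    def _result(self):
        inputs = {
            "c1": _container([_del("x", 1000, 5000), _del("p", 50_000, 60_000)]),
            "c2": _container([_del("y", 1010, 5010)]),
        }
        return merge_containers(inputs, "proximity", 100)

    def test_min_support_two_drops_private(self):
        res = filter_by_support(self._result(), 2)
        assert len(res.container) == 1
        assert res.membership["mergedid"].nunique() == 1

    def test_min_one_is_identity(self):
        before = self._result()
        after = filter_by_support(before, 1)
        assert len(after.container) == len(before.container)

    def test_min_above_caller_count_warns_and_empties(self):
        with pytest.warns(UserWarning, match="exceeds"):
            res = filter_by_support(self._result(), 5)
        assert len(res.container) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["proximity", "confidence_interval"])
    def test_random_instances_match_brute_force(self, mode):
        rng = np.random.default_rng(23)
        for trial in range(25):
            threshold = int(rng.integers(0, 300))
            containers = {
                caller: _container(random_breakend_records(rng, int(rng.integers(5, 45))))
                for caller in ("a", "b", "c")
            }
            res = merge_containers(containers, mode, threshold)
            assert _same_partition(
                res.cluster_labels(), oracle_clusters(containers, mode, threshold)
            )

    def test_caller_order_changes_only_representatives(self):
        rng = np.random.default_rng(31)
        containers = {
            caller: _container(random_breakend_records(rng, 30))
            for caller in ("a", "b", "c")
        }
        res1 = merge_containers(containers, "proximity", 150)
        reordered = {k: containers[k] for k in ("c", "a", "b")}
        res2 = merge_containers(reordered, "proximity", 150)
        assert _same_partition(res1.cluster_labels(), res2.cluster_labels())

    def test_zero_threshold_merges_only_exact_duplicates(self):
        inputs = {
            "c1": _container([_del("x", 1000, 5000), _del("w", 2000, 9000)]),
            "c2": _container([_del("y", 1000, 5000), _del("z", 2001, 9000)]),
        }
        labels = merge_containers(inputs, "proximity", 0).cluster_labels()
        assert labels[("c1", "x")] == labels[("c2", "y")]
        assert labels[("c1", "w")] != labels[("c2", "z")]

    def test_pointlike_ci_degenerates_to_zero_proximity(self):
        rng = np.random.default_rng(37)
        recs = random_breakend_records(rng, 40)
        stripped = []
        for r in recs:
            stripped.append(
                SVRecord(
                    id=r.id,
                    bp1=Breakend(r.bp1.chrom, r.bp1.pos, r.bp1.strand),
                    bp2=Breakend(r.bp2.chrom, r.bp2.pos, r.bp2.strand),
                    svtype=r.svtype,
                    svlen=r.svlen if r.svtype == "INS" else None,
                )
            )
        half = len(stripped) // 2
        inputs = {"a": _container(stripped[:half]), "b": _container(stripped[half:])}
        ci_labels = merge_containers(inputs, "confidence_interval").cluster_labels()
        prox_labels = merge_containers(inputs, "proximity", 0).cluster_labels()
        assert _same_partition(ci_labels, prox_labels)


class TestTruthRecovery:
    def test_shared_events_recovered_and_private_removed(self, sim_containers):
        containers, truth = sim_containers
        res = merge_containers(containers, "proximity", 100)
        res2 = filter_by_support(res, 2)
        tmap = dict(zip(zip(truth["caller"], truth["record_id"]), truth["truth_id"]))
        labels = res2.cluster_labels()
        # exactly the shared truth events remain
        shared_truth = set(truth[truth["shared"]]["truth_id"])
        assert {tmap[k] for k in labels} == shared_truth
        got = {}
        for k, v in labels.items():
            got.setdefault(v, set()).add(tmap[k])
        # each merged event maps to exactly one truth event and vice versa
        assert all(len(s) == 1 for s in got.values())
        assert len(got) == len(shared_truth)
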