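"""Refilling the relationship tree and cutting it into FunFams."""

import math

import numpy as np
import pytest

from funfamkit.alignment import identity_scheme
from funfamkit.conservation import ConservationParams
from funfamkit.core_model import DomainSequence, StartingCluster, check_partition
from funfamkit.distance_engine import DistanceHalfMatrix
from funfamkit.tree_build import agglomerate
from funfamkit.tree_cut import CutParams, cut, node_alignments, refill

SCHEME = identity_scheme()


def make_leaves(groups):
    """groups: {cluster_id: {seq_id: residues}} -> (clusters, sequences, matrix ids)."""
    clusters, sequences = [], {}
    for cid, members in groups.items():
        for sid, res in members.items():
            sequences[sid] = DomainSequence(sid, res)
        rep = sorted(members)[0]
        clusters.append(StartingCluster(cid, rep, set(members)))
    return clusters, sequences


def chain_matrix(ids, near=1.0, far=8.0):
    """First two ids are close; everything else is far from everything."""
    n = len(ids)
    square = np.full((n, n), far)
    np.fill_diagonal(square, 0.0)
    square[0, 1] = square[1, 0] = near
    return DistanceHalfMatrix.from_square(ids, square)


class TestRefill:
    def test_root_members_are_union(self):
        clusters, _ = make_leaves(
            {
                "c1": {f"x{i}": "ACD" for i in range(3)},
                "c2": {f"y{i}": "ACD" for i in range(5)},
            }
        )
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        tree = refill(agglomerate(m), clusters)
        assert len(tree.node_members[tree.root_id]) == 8

    def test_node_members_match_descendant_leaves(self):
        groups = {f"c{i}": {f"s{i}{j}": "ACDE" for j in range(i + 1)} for i in range(4)}
        clusters, _ = make_leaves(groups)
        m = chain_matrix(sorted(groups))
        tree = refill(agglomerate(m), clusters)
        by_id = {c.cluster_id: c.member_ids for c in clusters}
        for node, members in tree.node_members.items():
            expected = set().union(*(by_id[leaf] for leaf in tree.subtree_leaves(node)))
            assert set(members) == expected

    def test_missing_cluster_rejected(self):
        clusters, _ = make_leaves({"c1": {"s1": "ACD"}})
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        with pytest.raises(ValueError, match="without a matching cluster"):
            refill(agglomerate(m), clusters)


class TestNodeAlignments:
    def test_row_counts_equal_member_counts(self):
        groups = {
            "c1": {"a1": "ACDEF", "a2": "ACDEF"},
            "c2": {"b1": "ACDEF"},
            "c3": {"d1": "WYWYW", "d2": "WYWYW", "d3": "WYWYW"},
        }
        clusters, sequences = make_leaves(groups)
        m = chain_matrix(sorted(groups))
        tree = refill(agglomerate(m), clusters)
        alignments = node_alignments(tree, clusters, sequences, SCHEME)
        for node, members in tree.node_members.items():
            assert set(alignments[node].rows) == set(members)

    def test_identical_sequences_give_gap_free_root(self):
        groups = {"c1": {"a": "ACDE"}, "c2": {"b": "ACDE"}}
        clusters, sequences = make_leaves(groups)
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        tree = refill(agglomerate(m), clusters)
        root_msa = node_alignments(tree, clusters, sequences, SCHEME)[tree.root_id]
        assert set(root_msa.rows.values()) == {"ACDE"}


class TestCut:
    def test_single_cluster_tree_is_one_funfam(self):
        clusters, sequences = make_leaves({"c1": {"a": "ACD", "b": "ACD"}})
        from funfamkit.tree_build import RelationshipTree

        tree = RelationshipTree(leaves=["c1"], merges=[], root_id="c1")
        result = cut(tree, clusters, sequences, scheme=SCHEME)
        assert len(result.funfams) == 1
        assert result.funfams[0].member_ids == {"a", "b"}

    def test_same_function_leaves_merge_into_one_funfam(self):
        groups = {"c1": {"a1": "ACDEF", "a2": "ACDEF"}, "c2": {"b1": "ACDEF", "b2": "ACDEF"}}
        clusters, sequences = make_leaves(groups)
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        result = cut(agglomerate(m), clusters, sequences, scheme=SCHEME)
        assert len(result.funfams) == 1

    def test_planted_sdp_difference_splits_into_two_funfams(self):
        # conserved A vs conserved S at column 2
        groups = {"c1": {"a1": "ACAEF", "a2": "ACAEF"}, "c2": {"b1": "ACSEF", "b2": "ACSEF"}}
        clusters, sequences = make_leaves(groups)
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        result = cut(agglomerate(m), clusters, sequences, scheme=SCHEME)
        assert len(result.funfams) == 2
        assert result.dcp_counts[agglomerate(m).root_id] == 1

    @staticmethod
    def _planted_tree():
        groups = {
            "c1": {"a1": "ACAEF", "a2": "ACAEF"},
            "c2": {"b1": "ACSEF", "b2": "ACSEF"},
            "c3": {"d1": "WCSEF", "d2": "WCSEF"},
        }
        clusters, sequences = make_leaves(groups)
        m = chain_matrix(["c1", "c2", "c3"], near=1.0, far=5.0)
        return agglomerate(m), clusters, sequences

    def test_infinite_dcp_tolerance_gives_single_funfam(self):
        tree, clusters, sequences = self._planted_tree()
        params = CutParams(conservation=ConservationParams(d_max=math.inf))
        result = cut(tree, clusters, sequences, params, SCHEME)
        assert len(result.funfams) == 1

    def test_zero_ceiling_with_positive_distances_gives_leaves(self):
        tree, clusters, sequences = self._planted_tree()
        params = CutParams(
            conservation=ConservationParams(d_max=math.inf), distance_ceiling=0.0
        )
        result = cut(tree, clusters, sequences, params, SCHEME)
        assert len(result.funfams) == len(tree.leaves)

    def test_funfam_count_monotone_in_d_max(self):
        tree, clusters, sequences = self._planted_tree()
        counts = []
        for d_max in (0, 1, 2, math.inf):
            params = CutParams(conservation=ConservationParams(d_max=d_max))
            counts.append(len(cut(tree, clusters, sequences, params, SCHEME).funfams))
        assert counts == sorted(counts, reverse=True)

    def test_output_always_partitions_input(self):
        tree, clusters, sequences = self._planted_tree()
        result = cut(tree, clusters, sequences, scheme=SCHEME)
        union = check_partition(result.funfams)
        assert union == set(sequences)
        assert 1 <= len(result.funfams) <= len(tree.leaves)

    def test_size_floor_folds_singleton_into_neighbor(self):
        groups = {
            "c1": {"a1": "ACAEF", "a2": "ACAEF", "a3": "ACAEF"},
            "c2": {"b1": "ACSEF"},
        }
        clusters, sequences = make_leaves(groups)
        m = DistanceHalfMatrix(ids=["c1", "c2"], condensed=np.array([1.0]))
        params = CutParams(min_funfam_size=2)
        result = cut(agglomerate(m), clusters, sequences, params, SCHEME)
        assert len(result.funfams) == 1
        assert result.funfams[0].member_ids == {"a1", "a2", "a3", "b1"}
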