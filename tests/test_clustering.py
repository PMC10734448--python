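"""Tree-based strain clusters, NJ fallback, longitudinal tracks, MLST concordance."""

import numpy as np
import pandas as pd
import pytest

from straintrack.clustering import (assign_clusters, build_tracks,
                                    cluster_mlst_concordance, neighbor_joining,
                                    patristic_distances, read_tree,
                                    STATE_BOTH, STATE_CULTURE_ONLY,
                                    STATE_METAGENOME_ONLY, STATE_NEITHER)
from straintrack.distance import DistanceMatrix


def _random_caterpillar(rng, n_leaves):
    """Random rooted tree as nested (child, length) lists plus newick text."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.001, 0.1, 2).round(5)
        nodes.append(((a, la), (b, lb)))
    root = nodes[0]

    def walk(node):
        if isinstance(node, str):
            return node
        (a, la), (b, lb) = node
        return f"({walk(a)}:{la},{walk(b)}:{lb})"

    newick = walk(root) + ";"

    def leaves(node):
        if isinstance(node, str):
            return [node]
        (a, _), (b, _) = node
        return leaves(a) + leaves(b)

    def depth(sub, target, acc=0.0):
        if isinstance(sub, str):
            return acc if sub == target else None
        (p, dp), (q, dq) = sub
        left = depth(p, target, acc + dp)
        if left is not None:
            return left
        return depth(q, target, acc + dq)

    def pair_dist(node, x, y):
        # brute force: descend to the deepest subtree holding both leaves,
        # then sum root-to-leaf path lengths
        while not isinstance(node, str):
            (a, da), (b, db) = node
            moved = False
            for child, _ in ((a, da), (b, db)):
                sub = leaves(child)
                if x in sub and y in sub:
                    node = child
                    moved = True
                    break
            if not moved:
                break
        return depth(node, x) + depth(node, y)

    return newick, root, pair_dist


class TestPatristic:
    def test_two_leaf_path_sum(self):
        tree = read_tree("(A:0.004,B:0.003);")
        dm = patristic_distances(tree)
        i, j = dm.sample_ids.index("A"), dm.sample_ids.index("B")
        assert dm.rates[i, j] == pytest.approx(0.007)

    def test_zero_star_tree(self):
        tree = read_tree("(A:0.0,B:0.0,C:0.0,D:0.0);")
        assert np.allclose(patristic_distances(tree).rates, 0.0)

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(51)
        newick, root, pair_dist = _random_caterpillar(rng, 10)
        dm = patristic_distances(read_tree(newick))
        for i, x in enumerate(dm.sample_ids):
            for j in range(i + 1, len(dm.sample_ids)):
                y = dm.sample_ids[j]
                assert dm.rates[i, j] == pytest.approx(pair_dist(root, x, y), abs=1e-9)

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_tree("(A:0.1,A:0.2);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            read_tree("(A:0.1,B:0.2;")


TWO_CLADES = "((A:0.001,B:0.001):0.025,(C:0.001,D:0.001):0.025);"


class TestAssignClusters:
    def test_two_clades_at_default_threshold(self):
        asg = assign_clusters(read_tree(TWO_CLADES), 0.01)
        assert asg.labels == {"A": "A", "B": "A", "C": "B", "D": "B"}

    def test_zero_threshold_singletons(self):
        asg = assign_clusters(read_tree("((A:0.01,B:0.02):0.03,C:0.04);"), 0.0)
        assert asg.n_clusters == 3

    def test_threshold_above_diameter_single_cluster(self):
        asg = assign_clusters(read_tree(TWO_CLADES), 1.0)
        assert asg.n_clusters == 1

    def test_labels_follow_tip_order(self):
        asg = assign_clusters(read_tree("((Z:0.001,Y:0.001):0.05,(X:0.001,W:0.001):0.05);"),
                              0.01)
        assert asg.labels["Z"] == "A" and asg.labels["X"] == "B"

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(52)
        newick, _, _ = _random_caterpillar(rng, 12)
        tree = read_tree(newick)
        counts = [assign_clusters(tree, t).n_clusters
                  for t in (0.0, 0.005, 0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_to_rerooting(self):
        tree = read_tree(TWO_CLADES)
        partition = assign_clusters(tree, 0.01).labels
        rerooted = tree.root_at(list(tree.tips())[2].parent)
        partition2 = assign_clusters(rerooted, 0.01).labels
        # same partition regardless of labels
        groups = lambda p: {frozenset(k for k, v in p.items() if v == lab)
                            for lab in set(p.values())}
        assert groups(partition) == groups(partition2)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            assign_clusters(read_tree(TWO_CLADES), -0.1)


def _dm(ids, mat):
    mat = np.asarray(mat, dtype=float)
    return DistanceMatrix("sp", list(ids), mat, np.ones_like(mat, dtype=np.int64))


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # hand-drawn tree: ((A:2,B:3):1,(C:4,D:5)) -> additive matrix
        mat = [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]]
        tree = neighbor_joining(_dm("ABCD", mat))
        dm = patristic_distances(tree)
        idx = {s: i for i, s in enumerate(dm.sample_ids)}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert dm.rates[idx[a], idx[b]] == pytest.approx(mat[i][j], abs=1e-9)
        # AB vs CD split present: A-B path avoids C,D side
        assert dm.rates[idx["A"], idx["B"]] == pytest.approx(5)

    def test_three_equidistant_taxa_star(self):
        tree = neighbor_joining(_dm("ABC", [[0, 2, 2], [2, 0, 2], [2, 2, 0]]))
        dm = patristic_distances(tree)
        assert np.allclose(dm.rates[np.triu_indices(3, 1)], 2.0)

    def test_nan_rejected_with_guidance(self):
        mat = [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]
        with pytest.raises(ValueError, match="undefined distances"):
            neighbor_joining(_dm("ABC", mat))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(_dm("AB", [[0, 1], [1, 0]]))


class TestTracks:
    def _inputs(self):
        metadata = pd.DataFrame({
            "sample_id": ["P1.t1", "P1.t2", "P1.t3"],
            "subject_id": "P1",
            "timepoint": ["t1", "t2", "t3"],
            "dataset": "toy",
        })
        detection = pd.DataFrame({
            "sample_id": ["P1.t1", "P1.t2", "P1.t3"],
            "culture_positive": [1, 1, 0],
            "metagenome_positive": [1, 0, 0],
        })
        from straintrack.clustering import ClusterAssignment
        asg = ClusterAssignment({"P1.t1": "A"}, 0.01)
        mlst = pd.DataFrame({"sample_id": ["P1.t1"], "sequence_type": ["ST5"]})
        return asg, metadata, detection, mlst

    def test_four_state_legend(self):
        asg, metadata, detection, mlst = self._inputs()
        tracks = build_tracks(asg, metadata, detection, mlst)
        states = tracks.set_index("sample_id")["state"]
        assert states["P1.t1"] == STATE_BOTH
        assert states["P1.t2"] == STATE_CULTURE_ONLY
        assert states["P1.t3"] == STATE_NEITHER

    def test_cluster_attached_only_when_metagenome_positive(self):
        asg, metadata, detection, mlst = self._inputs()
        tracks = build_tracks(asg, metadata, detection, mlst).set_index("sample_id")
        assert tracks.loc["P1.t1", "cluster"] == "A"
        assert tracks.loc["P1.t2", "cluster"] is None
        assert tracks.loc["P1.t1", "sequence_type"] == "ST5"

    def test_metagenome_only_state(self):
        asg, metadata, detection, mlst = self._inputs()
        detection.loc[1, ["culture_positive", "metagenome_positive"]] = [0, 1]
        tracks = build_tracks(asg, metadata, detection, mlst).set_index("sample_id")
        assert tracks.loc["P1.t2", "state"] == STATE_METAGENOME_ONLY

    def test_unknown_mlst_sample_rejected(self):
        asg, metadata, detection, _ = self._inputs()
        mlst = pd.DataFrame({"sample_id": ["GHOST"], "sequence_type": ["ST1"]})
        with pytest.raises(KeyError, match="GHOST"):
            build_tracks(asg, metadata, detection, mlst)


class TestConcordance:
    def _asg(self, labels):
        from straintrack.clustering import ClusterAssignment
        return ClusterAssignment(labels, 0.01)

    def test_identical_partitions(self):
        asg = self._asg({"a": "A", "b": "A", "c": "B", "d": "B"})
        mlst = pd.DataFrame({"sample_id": list("abcd"),
                             "sequence_type": ["5", "5", "97", "97"]})
        assert cluster_mlst_concordance(asg, mlst) == pytest.approx(1.0)

    def test_singletons_vs_lump(self):
        asg = self._asg({s: lab for s, lab in zip("abcd", "ABCD")})
        mlst = pd.DataFrame({"sample_id": list("abcd"), "sequence_type": ["1"] * 4})
        assert cluster_mlst_concordance(asg, mlst) == pytest.approx(0.0)

    def test_invariant_to_label_permutation(self):
        base = {"a": "A", "b": "A", "c": "B", "d": "C"}
        perm = {"a": "C", "b": "C", "c": "A", "d": "B"}
        mlst = pd.DataFrame({"sample_id": list("abcd"),
                             "sequence_type": ["x", "x", "y", "z"]})
        assert cluster_mlst_concordance(self._asg(base), mlst) == pytest.approx(
            cluster_mlst_concordance(self._asg(perm), mlst))

    def test_too_few_colabeled_rejected(self):
        asg = self._asg({"a": "A"})
        mlst = pd.DataFrame({"sample_id": ["a"], "sequence_type": ["1"]})
        with pytest.raises(ValueError, match="at least 2"):
            cluster_mlst_concordance(asg, mlst)
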