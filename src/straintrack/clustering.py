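"""Strain clusters from a phylogenetic tree, longitudinal tracks, MLST concordance.

Strains are grouped by single-linkage agglomeration on patristic distances
(sum of branch lengths along the leaf-to-leaf path): two samples share a
cluster when a chain of pairwise distances, each at most the branch-length
threshold (default 0.01), connects them.  Patristic distances do not depend
on the root, so neither does the clustering.  Cluster labels are letters
A, B, ... assigned by each cluster's first leaf in the tree's tip order.

Clusters are then tracked per subject over time next to culture results and
MLST sequence types, with a four-state detection legend per timepoint:
neither / both / culture_only / metagenome_only.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj
from sklearn.metrics import adjusted_rand_score

from .distance import DistanceMatrix


def read_tree(source) -> TreeNode:
    """Parse a newick tree (path or string); leaves must be unique."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(StringIO(source))
    else:
        tree = TreeNode.read(str(source))
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf names in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name or 'internal node'}")
    return tree


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix, in tip order."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    mat = np.asarray(dm.data, dtype=float)
    return DistanceMatrix("", ids, mat, np.zeros_like(mat, dtype=np.int64))


def _letter_labels(n: int) -> list[str]:
    labels = []
    for i in range(n):
        s, k = "", i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, str]  # sample_id -> cluster letter
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["sample_id", "cluster"]
        )


def assign_clusters(tree: TreeNode, threshold: float = 0.01) -> ClusterAssignment:
    """Single-linkage clusters of leaves at a patristic-distance threshold.

    Leaves connected by any chain of pairwise patristic distances <= threshold
    share a cluster.  Deterministic: labels follow the tip order in the tree.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dm = patristic_distances(tree)
    if not dm.sample_ids:
        raise ValueError("tree has no leaves")
    adj = csr_matrix(dm.rates <= threshold)
    n_comp, comp = connected_components(adj, directed=False)
    # relabel components by first appearance in tip order
    order: dict[int, int] = {}
    for c in comp:
        if c not in order:
            order[c] = len(order)
    letters = _letter_labels(n_comp)
    labels = {
        sample: letters[order[c]] for sample, c in zip(dm.sample_ids, comp)
    }
    return ClusterAssignment(labels, threshold)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (plumbing fallback).

    Used when no externally built strain tree is supplied, so the synthetic
    pipeline closes without an external tree builder.  Requires >= 3 samples
    and fully defined distances; on additive matrices NJ recovers the
    generating topology and branch lengths.
    """
    if len(matrix.sample_ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if np.isnan(matrix.rates).any():
        raise ValueError(
            "undefined distances in matrix; drop samples with no shared "
            "positions before tree building"
        )
    dm = SkbioDistanceMatrix(matrix.rates, ids=matrix.sample_ids)
    tree = nj(dm)
    # NJ can emit tiny negative branch lengths from noise; clamp to zero
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


STATE_NEITHER = "neither"
STATE_BOTH = "both"
STATE_CULTURE_ONLY = "culture_only"
STATE_METAGENOME_ONLY = "metagenome_only"


def build_tracks(
    assignment: ClusterAssignment | None,
    metadata: pd.DataFrame,
    detection: pd.DataFrame,
    mlst: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Longitudinal per-subject table of detection states, clusters and STs.

    ``detection`` needs sample_id, culture_positive and metagenome_positive
    columns (0/1; NaN counts as 0).  A cluster label is attached only where
    the sample is metagenome-positive; an MLST sequence type wherever the
    isolate was typed.  Timepoints are ordered by their sort order within
    each subject.
    """
    labels = assignment.labels if assignment is not None else {}
    det = detection.set_index("sample_id")
    st_map: dict[str, str] = {}
    if mlst is not None and len(mlst):
        unknown = set(mlst["sample_id"]) - set(metadata["sample_id"])
        if unknown:
            raise KeyError(f"MLST table names unknown samples: {sorted(unknown)[:5]}")
        st_map = dict(zip(mlst["sample_id"], mlst["sequence_type"].astype(str)))

    rows = []
    for subject, grp in metadata.groupby("subject_id"):
        for _, rec in grp.sort_values("timepoint").iterrows():
            sample = rec["sample_id"]
            if sample in det.index:
                cul = int(det.loc[sample, "culture_positive"] == 1)
                met = int(det.loc[sample, "metagenome_positive"] == 1)
            else:
                cul = met = 0
            state = {
                (0, 0): STATE_NEITHER,
                (1, 1): STATE_BOTH,
                (1, 0): STATE_CULTURE_ONLY,
                (0, 1): STATE_METAGENOME_ONLY,
            }[(cul, met)]
            cluster = labels.get(sample) if met else None
            rows.append(
                (subject, rec["timepoint"], sample, state, cluster, st_map.get(sample))
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "timepoint", "sample_id", "state", "cluster", "sequence_type"],
    )


def cluster_mlst_concordance(
    assignment: ClusterAssignment, mlst: pd.DataFrame
) -> float:
    """Adjusted Rand index between the cluster partition and the ST partition.

    Computed over samples carrying both labels; 1 means the metagenomic
    clustering reproduces the typing scheme exactly, 0 is chance agreement.
    """
    co = [s for s in mlst["sample_id"] if s in assignment.labels]
    if len(co) < 2:
        raise ValueError("need at least 2 samples with both a cluster and an ST label")
    st = mlst.set_index("sample_id")["sequence_type"].astype(str)
    a = [assignment.labels[s] for s in co]
    b = [st.loc[s] for s in co]
    return float(adjusted_rand_score(a, b))
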