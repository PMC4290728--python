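import numpy as np
import pytest

from metaec.similarity import AbundanceProfile, PhyloTree, SimilarityMatrix


@pytest.fixture
def balanced_tree() -> PhyloTree:
    """((A:1,B:1):1,(C:1,D:1):1); — 4 leaves, 7 nodes, unit branches."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_profile_pair(tree: PhyloTree, rng: np.random.Generator):
    """Two random normalized profiles over the tree's leaves."""
    out = []
    for name in ("a", "b"):
        v = rng.dirichlet(np.ones(tree.n_leaves))
        out.append(AbundanceProfile(name, dict(zip(tree.leaf_names, v))))
    return out


def random_symmetric_w(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    A = rng.random((n, n))
    M = np.clip((A + A.T) / 2, 0.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix([f"s{i}" for i in range(n)], M)


def oracle_similarity(tree: PhyloTree, va: np.ndarray, vb: np.ndarray, decay: float) -> float:
    """Independent recursive (top-down call, bottom-up combine) scorer.

    Returns the total common abundance over all nodes, matching residual
    mass climbing toward the root attenuated by decay**branch_length.
    """
    leaf_of = np.full(tree.n_nodes, -1)
    leaf_of[tree.leaf_index] = np.arange(tree.n_leaves)

    def scale(node: int) -> float:
        return 0.0 if decay == 0.0 else decay ** tree.lengths[node]

    def rec(node: int):
        if tree.left[node] < 0:
            a, b = va[leaf_of[node]], vb[leaf_of[node]]
            c = min(a, b)
            return a - c, b - c, c
        ral, rbl, tl = rec(int(tree.left[node]))
        rar, rbr, tr = rec(int(tree.right[node]))
        a = ral * scale(int(tree.left[node])) + rar * scale(int(tree.right[node]))
        b = rbl * scale(int(tree.left[node])) + rbr * scale(int(tree.right[node]))
        c = min(a, b)
        return a - c, b - c, tl + tr + c

    return rec(tree.n_nodes - 1)[2]
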