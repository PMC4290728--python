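"""Phylogenetic structure similarity between metagenomic samples.

Two samples are compared on a shared rooted binary phylogenetic tree over
their taxa. At each leaf the *common abundance* is the smaller of the two
samples' abundances; unmatched (residual) abundance climbs toward the root,
attenuated per branch, and can match residual abundance from the other
sample at any ancestor. The similarity of a pair is the total common
abundance accumulated over all nodes — 1.0 for identical normalized
profiles, 0.0 for profiles with disjoint support when no residual is
allowed to propagate.

The attenuation is controlled by a single ``decay`` knob: residual mass
crossing a branch of length ``b`` is scaled by ``decay ** b``. ``decay=0``
disables propagation entirely (pure leaf overlap, a Bray–Curtis-style
score); ``decay=1`` lets all residual mass reach the root, where equal
leftover masses always match, so every pair scores exactly 1.0 — hence the
informative regime is strictly between 0 and 1 (default 0.5).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "AbundanceProfile",
    "SimilarityMatrix",
    "pairwise_similarity",
    "similarity_matrix",
    "threshold_network",
]

DEFAULT_DECAY = 0.5


class PhyloTree:
    """Rooted binary tree in flat arrays, postorder-indexed.

    Nodes are integers ``0..n_nodes-1`` in postorder (children precede
    parents, the root is last). Leaves carry taxon names; every node has a
    nonnegative branch length to its parent (0 at the root and wherever the
    source Newick omitted one). Non-binary input trees are binarized by
    inserting zero-length branches, so scores are unchanged for any decay.
    """

    def __init__(
        self,
        left: np.ndarray,
        right: np.ndarray,
        lengths: np.ndarray,
        leaf_names: Sequence[str],
        leaf_index: np.ndarray,
    ):
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.leaf_names = list(leaf_names)
        self.leaf_index = np.asarray(leaf_index, dtype=np.int64)
        self._validate()

    def _validate(self) -> None:
        n = self.n_nodes
        if len(self.right) != n or len(self.lengths) != n:
            raise ValueError("left/right/lengths arrays must have equal length")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be nonnegative")
        is_leaf = self.left < 0
        if np.any(is_leaf != (self.right < 0)):
            raise ValueError("every internal node must have exactly two children")
        if len(self.leaf_names) != len(set(self.leaf_names)):
            raise ValueError("leaf names must be unique")
        if len(self.leaf_names) != int(is_leaf.sum()):
            raise ValueError("leaf_names must cover every leaf exactly once")
        # children precede parents under postorder numbering
        internal = np.flatnonzero(~is_leaf)
        if internal.size and (
            np.any(self.left[internal] >= internal) or np.any(self.right[internal] >= internal)
        ):
            raise ValueError("nodes must be numbered in postorder")
        self._name_to_node = {
            name: int(node) for name, node in zip(self.leaf_names, self.leaf_index)
        }

    @property
    def n_nodes(self) -> int:
        return len(self.left)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaf_node(self, name: str) -> int:
        try:
            return self._name_to_node[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} is not a leaf of the tree") from None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        # a bifurcating root of degree 2 is what we need; suppress unifurcations
        tree.suppress_unifurcations()
        left, right, lengths = [], [], []
        leaf_names, leaf_index = [], []
        index: dict = {}
        for nd in tree.postorder_node_iter():
            children = nd.child_nodes()
            if len(children) == 0:
                left.append(-1)
                right.append(-1)
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise ValueError("unlabeled leaf in Newick tree")
                leaf_names.append(str(label))
                leaf_index.append(len(left) - 1)
            elif len(children) == 2:
                left.append(index[id(children[0])])
                right.append(index[id(children[1])])
            else:  # pragma: no cover - resolve_polytomies guarantees binary
                raise ValueError("tree is not binary after polytomy resolution")
            index[id(nd)] = len(left) - 1
            bl = nd.edge.length
            lengths.append(float(bl) if bl is not None else 0.0)
        lengths[-1] = 0.0  # root branch irrelevant
        return cls(np.array(left), np.array(right), np.array(lengths), leaf_names, np.array(leaf_index))

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string or file path (branch lengths optional)."""
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def random(cls, n_leaves: int, rng: np.random.Generator, branch_scale: float = 0.1) -> "PhyloTree":
        """Random bifurcating topology by iterative joins; Exp branch lengths."""
        if n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        left = [-1] * n_leaves
        right = [-1] * n_leaves
        lengths = list(rng.exponential(branch_scale, size=n_leaves))
        leaf_names = [f"t{i}" for i in range(n_leaves)]
        live = list(range(n_leaves))
        while len(live) > 1:
            i, j = sorted(rng.choice(len(live), size=2, replace=False))
            a, b = live[i], live[j]
            left.append(a)
            right.append(b)
            lengths.append(float(rng.exponential(branch_scale)))
            live.pop(j)
            live.pop(i)
            live.append(len(left) - 1)
        lengths[-1] = 0.0
        order = _postorder_permutation(np.array(left), np.array(right))
        return cls._renumber(np.array(left), np.array(right), np.array(lengths), leaf_names, order)

    @classmethod
    def _renumber(cls, left, right, lengths, leaf_names, order) -> "PhyloTree":
        pos = np.empty(len(order), dtype=np.int64)
        pos[order] = np.arange(len(order))
        new_left = np.where(left[order] >= 0, pos[np.maximum(left[order], 0)], -1)
        new_right = np.where(right[order] >= 0, pos[np.maximum(right[order], 0)], -1)
        leaf_index = pos[np.arange(len(leaf_names))]
        return cls(new_left, new_right, lengths[order], leaf_names, leaf_index)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.left[node] < 0:
                name = self.leaf_names[int(np.flatnonzero(self.leaf_index == node)[0])]
            else:
                name = f"({render(int(self.left[node]))},{render(int(self.right[node]))})"
            return f"{name}:{self.lengths[node]:.10g}"

        root = self.n_nodes - 1
        return f"({render(int(self.left[root]))},{render(int(self.right[root]))});"


def _postorder_permutation(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    root = len(left) - 1
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done or left[node] < 0:
            order.append(node)
        else:
            stack.append((node, True))
            stack.append((int(right[node]), False))
            stack.append((int(left[node]), False))
    return np.array(order, dtype=np.int64)


@dataclass
class AbundanceProfile:
    """Relative abundances of one sample over the leaf taxa of a shared tree."""

    sample_id: str
    abundance: Mapping[str, float]

    def __post_init__(self) -> None:
        self.abundance = {str(k): float(v) for k, v in dict(self.abundance).items()}
        if any(v < 0 for v in self.abundance.values()):
            bad = next(k for k, v in self.abundance.items() if v < 0)
            raise ValueError(f"negative abundance for taxon {bad!r} in sample {self.sample_id!r}")

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= 1e-9

    def normalize(self) -> "AbundanceProfile":
        t = self.total
        if t <= 0:
            raise ValueError(f"sample {self.sample_id!r} has zero total abundance")
        return AbundanceProfile(self.sample_id, {k: v / t for k, v in self.abundance.items()})

    def as_vector(self, tree: PhyloTree) -> np.ndarray:
        """Dense leaf-ordered vector; taxa absent from the profile are 0."""
        vec = np.zeros(tree.n_leaves)
        name_pos = {name: i for i, name in enumerate(tree.leaf_names)}
        for taxon, value in self.abundance.items():
            if taxon not in name_pos:
                raise KeyError(f"taxon {taxon!r} (sample {self.sample_id!r}) is not in the tree")
            vec[name_pos[taxon]] = value
        return vec


@dataclass
class SimilarityMatrix:
    """N x N symmetric matrix of pairwise sample similarities in [0, 1].

    The same container holds the consensus matrix W of the ensemble stage
    and, after thresholding, the adjacency of the similarity network.
    """

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} sample ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite entry at ({self.sample_ids[i]}, {self.sample_ids[j]})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("matrix is not symmetric within 1e-12")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def _decay_scales(tree: PhyloTree, decay: float) -> np.ndarray:
    if decay == 0.0:
        return np.zeros(tree.n_nodes)
    return np.power(decay, tree.lengths)


def _similarity_kernel(
    tree: PhyloTree, A: np.ndarray, B: np.ndarray, decay: float
) -> np.ndarray:
    """Total common abundance for P aligned pairs. A, B: (P, n_leaves)."""
    P = A.shape[0]
    scales = _decay_scales(tree, decay)
    res_a = np.zeros((tree.n_nodes, P))
    res_b = np.zeros((tree.n_nodes, P))
    total = np.zeros(P)
    leaf_of = np.full(tree.n_nodes, -1, dtype=np.int64)
    leaf_of[tree.leaf_index] = np.arange(tree.n_leaves)
    for node in range(tree.n_nodes):
        l, r = tree.left[node], tree.right[node]
        if l < 0:
            arr_a = A[:, leaf_of[node]].copy()
            arr_b = B[:, leaf_of[node]].copy()
        else:
            arr_a = res_a[l] * scales[l] + res_a[r] * scales[r]
            arr_b = res_b[l] * scales[l] + res_b[r] * scales[r]
        common = np.minimum(arr_a, arr_b)
        total += common
        res_a[node] = arr_a - common
        res_b[node] = arr_b - common
    return total


def pairwise_similarity(
    a: AbundanceProfile,
    b: AbundanceProfile,
    tree: PhyloTree,
    decay: float = DEFAULT_DECAY,
    normalize: bool = False,
) -> float:
    """Phylogenetic structure similarity of two samples, in [0, 1].

    Both profiles must be L1-normalized (or pass ``normalize=True`` to
    normalize on the fly). Symmetric in its two profile arguments.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError("decay must lie in [0, 1]")
    if normalize:
        a, b = a.normalize(), b.normalize()
    for p in (a, b):
        if not p.is_normalized:
            raise ValueError(
                f"profile {p.sample_id!r} is not normalized (sum={p.total:.6g}); "
                "pass normalize=True to normalize on load"
            )
    va = a.as_vector(tree)[None, :]
    vb = b.as_vector(tree)[None, :]
    return float(np.clip(_similarity_kernel(tree, va, vb, decay)[0], 0.0, 1.0))


def similarity_matrix(
    profiles: Sequence[AbundanceProfile],
    tree: PhyloTree,
    decay: float = DEFAULT_DECAY,
    workers: int = 1,
    normalize: bool = False,
) -> SimilarityMatrix:
    """All-pairs similarity matrix; identical for any worker count."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if workers < 1:
        raise ValueError("workers must be a positive integer")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in profile list")
    if normalize:
        profiles = [p if p.is_normalized else p.normalize() for p in profiles]
    for p in profiles:
        if not p.is_normalized:
            raise ValueError(
                f"profile {p.sample_id!r} is not normalized; pass normalize=True"
            )
    X = np.stack([p.as_vector(tree) for p in profiles])
    n = len(profiles)
    iu, ju = np.triu_indices(n, k=1)
    chunks = np.array_split(np.arange(len(iu)), min(workers, max(1, len(iu))))

    def work(idx: np.ndarray) -> np.ndarray:
        return _similarity_kernel(tree, X[iu[idx]], X[ju[idx]], decay)

    if workers == 1:
        parts = [work(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(work, chunks))
    vals = np.clip(np.concatenate(parts), 0.0, 1.0)
    M = np.eye(n)
    M[iu, ju] = vals
    M[ju, iu] = vals
    return SimilarityMatrix(ids, M)


def threshold_network(m: SimilarityMatrix, t: float) -> SimilarityMatrix:
    """Zero out off-diagonal entries below ``t``; diagonal untouched."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = m.values.copy()
    off = ~np.eye(m.n, dtype=bool)
    vals[off & (vals < t)] = 0.0
    return SimilarityMatrix(list(m.sample_ids), vals)
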