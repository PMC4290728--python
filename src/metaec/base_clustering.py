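"""Generation phase: base clustering results on the similarity network.

Four clustering families, each taking a different "look" at the network:
distribution-based (Gaussian mixture fit by EM), K-means, agglomerative
hierarchical clustering with average linkage, and density-based scanning
(DBSCAN). The vector-space algorithms (EM, K-means) consume each sample's
row of the similarity matrix as its feature vector; the distance-based
ones operate on 1 - similarity. Density-based clustering may leave samples
unassigned; these keep the reserved NOISE label (-1) and are handled
downstream by the consensus matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from .similarity import SimilarityMatrix

__all__ = ["NOISE", "ALGORITHMS", "Partition", "EnsembleConfig", "run_base_clusterer", "generate_ensemble"]

logger = logging.getLogger(__name__)

NOISE = -1
ALGORITHMS = ("em", "kmeans", "hierarchical", "density")


@dataclass
class Partition:
    """One base clustering result: per-sample integer labels, NOISE = -1."""

    sample_ids: list[str]
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length must equal number of samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.labels < NOISE):
            raise ValueError("labels must be >= -1 (NOISE)")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != NOISE].tolist()))

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for sid, lab in zip(self.sample_ids, self.labels):
            if lab != NOISE:
                out.setdefault(int(lab), set()).add(sid)
        return out


@dataclass
class EnsembleConfig:
    """Grid of (algorithm, parameter grid, seeds) entries.

    ``grid`` maps parameter name to a list of values; the cartesian
    product of the grid crossed with the seeds defines the runs. For the
    deterministic algorithms (hierarchical, density) seeds are ignored and
    a single run per parameter point is made.
    """

    entries: list[tuple[str, Mapping[str, Sequence[Any]], Sequence[int]]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("ensemble config needs at least one entry")
        for algo, grid, seeds in self.entries:
            if algo not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")
            if not grid or any(len(v) == 0 for v in grid.values()):
                raise ValueError(f"empty parameter grid for {algo!r}")
        if sum(1 for _ in self.runs()) < 2:
            raise ValueError("config must define an ensemble of size >= 2")

    def runs(self) -> Iterator[tuple[str, dict, int]]:
        for algo, grid, seeds in self.entries:
            keys = sorted(grid)
            for combo in itertools.product(*(grid[k] for k in keys)):
                params = dict(zip(keys, combo))
                use_seeds = seeds if algo in ("em", "kmeans") else [0]
                for seed in use_seeds:
                    yield algo, params, int(seed)

    @classmethod
    def default(
        cls,
        k_values: Sequence[int] = (6, 7, 8, 9, 10),
        seeds: Sequence[int] = (0, 1, 2),
        eps_values: Sequence[float] = (0.1, 0.2, 0.3),
        min_pts: int = 4,
    ) -> "EnsembleConfig":
        return cls(
            [
                ("em", {"k": list(k_values)}, list(seeds)),
                ("kmeans", {"k": list(k_values)}, list(seeds)),
                ("hierarchical", {"k": list(k_values)}, [0]),
                ("density", {"eps": list(eps_values), "min_pts": [min_pts]}, [0]),
            ]
        )


def run_base_clusterer(
    m: SimilarityMatrix, algorithm: str, params: Mapping[str, Any], seed: int = 0
) -> Partition:
    """Run one base clustering algorithm on the similarity network.

    Deterministic given (matrix, algorithm, params, seed).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    n = m.n
    if n == 0:
        raise ValueError("empty similarity matrix")
    X = m.values
    if algorithm in ("em", "kmeans", "hierarchical"):
        k = int(params["k"])
        if k < 2 or k > n:
            raise ValueError(f"k={k} out of range [2, {n}]")
    if algorithm == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    elif algorithm == "em":
        labels = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            random_state=seed,
            reg_covar=1e-6,
            max_iter=200,
        ).fit_predict(X)
    elif algorithm == "hierarchical":
        D = 1.0 - X
        np.fill_diagonal(D, 0.0)
        labels = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        ).fit_predict(D)
    else:  # density
        eps = float(params["eps"])
        min_pts = int(params.get("min_pts", 4))
        D = np.clip(1.0 - X, 0.0, None)
        np.fill_diagonal(D, 0.0)
        labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit_predict(D)
    return Partition(
        list(m.sample_ids),
        np.asarray(labels, dtype=np.int64),
        provenance={"algorithm": algorithm, "params": dict(params), "seed": int(seed)},
    )


def generate_ensemble(m: SimilarityMatrix, cfg: EnsembleConfig) -> list[Partition]:
    """One Partition per (algorithm, parameter point, seed), order-stable.

    Individual failing runs are logged and skipped; fewer than two
    surviving results is an error.
    """
    out: list[Partition] = []
    for algo, params, seed in cfg.runs():
        try:
            out.append(run_base_clusterer(m, algo, params, seed))
        except Exception as exc:  # noqa: BLE001 - contract: log and skip
            logger.warning("base run %s %s seed=%d failed: %s", algo, params, seed, exc)
    if len(out) < 2:
        raise RuntimeError("fewer than 2 base clustering results survived")
    return out
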