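"""Identification phase: symmetric NMF of the consensus matrix.

The consensus matrix W is approximated as H Hᵀ with H ≥ 0 (N samples ×
K clusters); h_{i,z} is the real-valued membership of sample i in
cluster z. The fit minimizes the generalized Kullback–Leibler divergence
D_KL(W ‖ HHᵀ) plus an L1 penalty β·Σ h that keeps each sample's
membership row sparse. Dropping terms constant in H, the objective is

    F(H) = −Σ_ij [ W_ij log (HHᵀ)_ij − (HHᵀ)_ij ] + β Σ_iz h_iz.

H is estimated by a damped multiplicative update (half old value, half
multiplicatively rescaled value):

    h_iz ← h_iz/2 + ½ · h_iz · [Σ_j W_ij h_jz / (HHᵀ)_ij] / (Σ_j h_jz + β/2)

which preserves nonnegativity, locks zero entries at zero, and decreases
F monotonically. Iteration stops when ‖H_l − H_{l−1}‖₁ < ρ (default
1e−6) or after 200 iterations; the factorization is restarted from 10
random initial conditions and the run with the lowest objective is kept.
Real-valued memberships are binarized with a threshold τ, allowing a
sample to belong to several clusters or to none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .base_clustering import NOISE, Partition
from .similarity import SimilarityMatrix

__all__ = [
    "EPS",
    "FactorizationResult",
    "Community",
    "kl_objective",
    "update_H",
    "factorize",
    "init_from_partition",
    "threshold_membership",
]

EPS = 1e-12  # floor for denominators and log arguments
INIT_FLOOR = 1e-3  # membership floor for partition-seeded starts


@dataclass
class FactorizationResult:
    H: np.ndarray
    cost_trace: list[float]
    iterations: int
    converged: bool
    restart_index: int

    @property
    def cost(self) -> float:
        return self.cost_trace[-1]


@dataclass
class Community:
    """K possibly-overlapping clusters plus the unassigned remainder."""

    sample_ids: list[str]
    clusters: list[set[str]]
    unassigned: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        covered = set().union(*self.clusters) if self.clusters else set()
        universe = set(self.sample_ids)
        if not covered <= universe or not self.unassigned <= universe:
            raise ValueError("cluster members must be drawn from sample_ids")
        if covered | self.unassigned != universe:
            raise ValueError("clusters plus unassigned must cover all samples")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership_of(self, sample_id: str) -> list[int]:
        return [z for z, c in enumerate(self.clusters) if sample_id in c]

    @classmethod
    def from_partition(cls, p: Partition) -> "Community":
        """View a hard partition as a community; NOISE becomes unassigned."""
        clusters = [members for _, members in sorted(p.clusters().items())]
        noise = {s for s, lab in zip(p.sample_ids, p.labels) if lab == NOISE}
        return cls(list(p.sample_ids), clusters, noise)


def _check_H(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2:
        raise ValueError("H must be a 2-D matrix")
    if np.any(H < 0):
        raise ValueError("H must be nonnegative")
    if not np.all(np.isfinite(H)):
        raise ValueError("H must be finite")
    return H


def kl_objective(W: SimilarityMatrix | np.ndarray, H: np.ndarray, beta: float = 1.0) -> float:
    """Sparsity-regularized KL objective F(H); lower is a better fit."""
    Wv = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=np.float64)
    H = _check_H(H)
    if H.shape[0] != Wv.shape[0]:
        raise ValueError("W and H dimensions disagree")
    WH = H @ H.T
    log_term = Wv * np.log(np.maximum(WH, EPS))
    return float(-(np.sum(log_term) - np.sum(WH)) + beta * np.sum(H))


def update_H(W: SimilarityMatrix | np.ndarray, H: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """One damped multiplicative update step; zeros stay zero."""
    Wv = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=np.float64)
    H = _check_H(H)
    WH = np.maximum(H @ H.T, EPS)
    numer = (Wv / WH) @ H  # (i,z): Σ_j W_ij h_jz / (HHᵀ)_ij
    denom = np.maximum(H.sum(axis=0) + 0.5 * beta, EPS)  # (z,)
    return 0.5 * H + 0.5 * H * numer / denom[None, :]


def _random_init(W: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random soft-assignment rows, rescaled so mean(HHᵀ) matches mean(W).

    Each row is a Dirichlet(½) draw over the K clusters (floored at 1e-3
    so no entry is frozen by the multiplicative updates): every sample
    starts leaning toward a random cluster, which breaks the symmetry
    between columns that makes i.i.d. starts prone to merge/split local
    minima, while remaining a random initial condition.
    """
    U = np.maximum(rng.dirichlet(np.full(K, 0.5), size=W.shape[0]), INIT_FLOOR)
    mean_uu = float(np.mean(U @ U.T))
    target = max(float(np.mean(W)), EPS)
    return U * np.sqrt(target / max(mean_uu, EPS))


def factorize(
    W: SimilarityMatrix,
    K: int,
    beta: float = 1.0,
    rho: float = 1e-6,
    max_iter: int = 200,
    restarts: int = 10,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
) -> FactorizationResult:
    """Fit W ≈ HHᵀ, returning the best of several restarts.

    With ``init`` given (a membership matrix, e.g. built from a base
    clustering result via :func:`init_from_partition`), a single run from
    that start is made instead of random restarts.
    """
    Wv = W.values
    N = Wv.shape[0]
    if not 2 <= K <= N:
        raise ValueError(f"K={K} out of range [2, {N}]")
    if rho <= 0 or beta < 0 or max_iter < 1 or restarts < 1:
        raise ValueError("invalid solver parameters")
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray]
    if init is not None:
        init = _check_H(init)
        if init.shape != (N, K):
            raise ValueError(f"init shape {init.shape} != ({N}, {K})")
        starts = [init.copy()]
    else:
        starts = [_random_init(Wv, K, rng) for _ in range(restarts)]

    best: FactorizationResult | None = None
    for r, H in enumerate(starts):
        trace = [kl_objective(Wv, H, beta)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            H_new = update_H(Wv, H, beta)
            trace.append(kl_objective(Wv, H_new, beta))
            delta = float(np.abs(H_new - H).sum())
            H = H_new
            if delta < rho:
                converged = True
                break
        cand = FactorizationResult(H, trace, it, converged, r)
        if best is None or cand.cost < best.cost:
            best = cand
    assert best is not None
    return best


def init_from_partition(p: Partition, K: int) -> np.ndarray:
    """Membership matrix seeded from a base clustering result.

    Member entries are 1; everything else (including filler columns when
    the partition has fewer than K clusters, and the rows of NOISE
    samples) gets a small positive floor — a pure 0/1 start would freeze
    the zeros under multiplicative updates.
    """
    labels = sorted(set(p.labels[p.labels != NOISE].tolist()))
    if len(labels) > K:
        raise ValueError(f"partition has {len(labels)} clusters, more than K={K}")
    col = {lab: z for z, lab in enumerate(labels)}
    H = np.full((len(p.sample_ids), K), INIT_FLOOR)
    for i, lab in enumerate(p.labels):
        if lab != NOISE:
            H[i, col[int(lab)]] = 1.0
    return H


def threshold_membership(
    H: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    tau: float = 0.5,
    row_normalize: bool = False,
) -> Community:
    """Binarize memberships: sample i joins cluster z iff h_iz ≥ τ.

    With ``row_normalize=True`` each row is first scaled to unit maximum,
    making τ a fraction of the sample's strongest membership (the
    pipeline default; scale-invariant, so τ needn't track β). Samples
    whose row never reaches τ (or is all zero) are left unassigned; empty
    clusters are dropped with a warning.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    H = _check_H(H)
    N, K = H.shape
    if sample_ids is None:
        sample_ids = [str(i) for i in range(N)]
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != N:
        raise ValueError("sample_ids length must match H rows")
    Hs = H
    if row_normalize:
        rowmax = H.max(axis=1, keepdims=True)
        Hs = np.divide(H, rowmax, out=np.zeros_like(H), where=rowmax > 0)
    member = Hs >= tau
    clusters = []
    for z in range(K):
        c = {sample_ids[i] for i in np.flatnonzero(member[:, z])}
        if c:
            clusters.append(c)
        else:
            warnings.warn(f"dropping empty cluster {z}", stacklevel=2)
    assigned = set().union(*clusters) if clusters else set()
    unassigned = set(sample_ids) - assigned
    return Community(sample_ids, clusters, unassigned)
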