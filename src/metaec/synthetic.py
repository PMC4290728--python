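"""Synthetic fixtures with known ground truth.

Two generators at desk scale (~120 samples, 64 taxa — the full pipeline
runs in well under a minute at this size):

* :func:`planted_similarity` — block-structured similarity matrices
  (a planted partition): within-block entries drawn around ``mu_in``,
  between-block around ``mu_out``, clipped to [0, 1] and symmetrized.
* :func:`synth_profiles` — a random bifurcating phylogeny plus
  class-structured abundance profiles. Each meta-class gets its own
  sparse Dirichlet center over the leaf taxa; its samples are Dirichlet
  draws concentrated around that center, so within-class phylogenetic
  similarity exceeds between-class similarity by an amount set by the
  ``dispersion`` knob. Default per-class sample counts follow the
  observed 1920-sample meta-class census (331, 698, 366, 130, 262, 133
  over male/female × gut/skin/oral) scaled to the requested total by
  largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evaluation import GENDERS, HABITATS, MetaLabels
from .similarity import AbundanceProfile, PhyloTree, SimilarityMatrix

__all__ = ["META_CLASS_CENSUS", "PlantedTruth", "planted_similarity", "synth_profiles", "scaled_class_counts"]

# male×(gut,skin,oral) then female×(gut,skin,oral)
META_CLASS_CENSUS = (331, 698, 366, 130, 262, 133)

# Dirichlet concentration of the class centers: < 1 makes each class
# dominated by its own handful of taxa, as distinct community types are.
CENTER_ALPHA = 0.2
# Concentration of samples around their class center; ~500 puts
# within-class similarity above 0.9 and between-class around 0.6, the
# regime where 0.7-0.9 edge thresholds on the network are meaningful.
DEFAULT_DISPERSION = 500.0


@dataclass
class PlantedTruth:
    """Ground truth of a planted-partition similarity matrix."""

    block_sizes: list[int]
    block_of: np.ndarray  # per-sample true block id
    mu_in: float
    mu_out: float
    sigma: float
    seed: int

    def reference(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for i, b in enumerate(self.block_of):
            out.setdefault(int(b), set()).add(f"s{i}")
        return out


def planted_similarity(
    sizes: Sequence[int],
    mu_in: float = 0.9,
    mu_out: float = 0.2,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[SimilarityMatrix, PlantedTruth]:
    """Block-diagonal planted-partition similarity matrix."""
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("block sizes must be positive")
    if not (0 <= mu_out < mu_in <= 1):
        raise ValueError("need 0 <= mu_out < mu_in <= 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    same = block_of[:, None] == block_of[None, :]
    mu = np.where(same, mu_in, mu_out)
    vals = mu + (rng.normal(0.0, sigma, size=(n, n)) if sigma > 0 else 0.0)
    iu = np.triu_indices(n, k=1)
    M = np.eye(n)
    M[iu] = np.clip(vals[iu], 0.0, 1.0)
    M = np.maximum(M, M.T)
    ids = [f"s{i}" for i in range(n)]
    return SimilarityMatrix(ids, M), PlantedTruth(sizes, block_of, mu_in, mu_out, sigma, seed)


def scaled_class_counts(total: int, census: Sequence[int] = META_CLASS_CENSUS) -> list[int]:
    """Scale the meta-class census to ``total`` samples (largest remainder)."""
    census = np.asarray(census, dtype=float)
    quota = census / census.sum() * total
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for idx in np.argsort(-rem)[: total - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def synth_profiles(
    n_leaves: int = 64,
    class_centers: int = 6,
    samples_per_class: Optional[Sequence[int]] = None,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    branch_scale: float = 0.3,
) -> tuple[PhyloTree, list[AbundanceProfile], MetaLabels]:
    """Tree + class-structured profiles + meta-labels with planted truth.

    Classes map onto meta-classes in census order (male-gut, male-skin,
    male-oral, female-gut, female-skin, female-oral); with fewer than 6
    classes only the first ``class_centers`` meta-classes are used.
    """
    if not 1 <= class_centers <= 6:
        raise ValueError("class_centers must be in 1..6")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if samples_per_class is None:
        samples_per_class = scaled_class_counts(120, META_CLASS_CENSUS[:class_centers])
    samples_per_class = [int(c) for c in samples_per_class]
    if len(samples_per_class) != class_centers:
        raise ValueError("samples_per_class length must equal class_centers")
    rng = np.random.default_rng(seed)
    tree = PhyloTree.random(n_leaves, rng, branch_scale=branch_scale)
    meta = [(g, h) for g in GENDERS for h in HABITATS][:class_centers]
    profiles: list[AbundanceProfile] = []
    habitat: dict[str, str] = {}
    gender: dict[str, str] = {}
    for k, ((g, h), n_k) in enumerate(zip(meta, samples_per_class)):
        center = rng.dirichlet(np.full(n_leaves, CENTER_ALPHA))
        alpha = np.maximum(center * dispersion, 1e-8)
        draws = rng.dirichlet(alpha, size=n_k)
        for j in range(n_k):
            sid = f"{g}_{h}_{j}"
            vec = draws[j] / draws[j].sum()
            profiles.append(
                AbundanceProfile(sid, dict(zip(tree.leaf_names, vec)))
            )
            habitat[sid] = h
            gender[sid] = g
    return tree, profiles, MetaLabels(habitat, gender)
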