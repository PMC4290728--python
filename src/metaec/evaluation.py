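"""Scoring detected communities against meta-class reference clusters.

Reference clusters group samples sharing a meta-class — the cross of
body habitat {gut, skin, oral} and host gender {male, female}, six
classes in all. Three complementary scores are computed, each in [0, 1]
with 1 a perfect match:

* ``f_measure`` — cluster-level matching. A detected cluster matches a
  reference cluster when their neighborhood affinity
  |C_p ∩ C_r|² / (|C_p|·|C_r|) reaches ω (default 0.25). Precision is
  the fraction of detected clusters matched, recall the fraction of
  reference clusters matched, f their harmonic mean.
* ``pr_metric`` — pair-level agreement: precision and recall of
  co-membership over all unordered sample pairs (a pair counts once even
  when the clusters overlap), combined as a harmonic mean.
* ``f_score`` — per reference class, the best F1 over detected clusters,
  averaged with weights proportional to class size.

These formulations follow the community-detection literature; alternate
definitions can be swapped in via the ``matcher`` hook of f_measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix
from .symnmf import Community

__all__ = [
    "HABITATS",
    "GENDERS",
    "MetaLabels",
    "reference_clusters",
    "neighborhood_affinity",
    "f_measure",
    "pr_metric",
    "f_score",
    "composite_score",
    "composition_table",
    "gender_variation",
]

HABITATS = ("gut", "skin", "oral")
GENDERS = ("male", "female")
META_CLASSES = tuple(f"{g}&{h}" for g in GENDERS for h in HABITATS)


@dataclass
class MetaLabels:
    """Per-sample habitat and gender annotations."""

    habitat: dict[str, str]
    gender: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.habitat) != set(self.gender):
            raise ValueError("habitat and gender must label the same samples")
        for s, h in self.habitat.items():
            if h not in HABITATS:
                raise ValueError(f"unknown habitat {h!r} for sample {s!r}")
        for s, g in self.gender.items():
            if g not in GENDERS:
                raise ValueError(f"unknown gender {g!r} for sample {s!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.habitat)

    def meta_class(self, sample_id: str) -> str:
        return f"{self.gender[sample_id]}&{self.habitat[sample_id]}"


def reference_clusters(labels: MetaLabels) -> dict[str, set[str]]:
    """Disjoint reference clusters, one per occupied meta-class."""
    out: dict[str, set[str]] = {}
    for s in labels.sample_ids:
        out.setdefault(labels.meta_class(s), set()).add(s)
    return out


def _as_reference_sets(reference) -> list[set[str]]:
    if isinstance(reference, Mapping):
        return [set(v) for v in reference.values()]
    return [set(v) for v in reference]


def neighborhood_affinity(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def f_measure(
    detected: Community,
    reference,
    omega: float = 0.25,
    matcher: Callable[[set, set], float] = neighborhood_affinity,
) -> tuple[float, float, float]:
    """Cluster-level (precision, recall, f) under affinity matching."""
    if not detected.clusters:
        raise ValueError("no detected clusters")
    refs = _as_reference_sets(reference)
    if not refs:
        raise ValueError("no reference clusters")
    aff = np.array([[matcher(c, r) for r in refs] for c in detected.clusters])
    matched_det = int(np.sum(aff.max(axis=1) >= omega))
    matched_ref = int(np.sum(aff.max(axis=0) >= omega))
    precision = matched_det / len(detected.clusters)
    recall = matched_ref / len(refs)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


def _co_membership(clusters: Sequence[set[str]], order: Mapping[str, int], n: int) -> np.ndarray:
    co = np.zeros((n, n), dtype=bool)
    for c in clusters:
        idx = np.array(sorted(order[s] for s in c), dtype=np.int64)
        co[np.ix_(idx, idx)] = True
    np.fill_diagonal(co, False)
    return co


def pr_metric(detected: Community, reference) -> float:
    """Harmonic mean of pairwise co-membership precision and recall."""
    ids = detected.sample_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    order = {s: i for i, s in enumerate(ids)}
    det = _co_membership(detected.clusters, order, n)
    ref = _co_membership(_as_reference_sets(reference), order, n)
    tp = np.sum(det & ref) / 2
    n_det = np.sum(det) / 2
    n_ref = np.sum(ref) / 2
    precision = float(tp / n_det) if n_det > 0 else 0.0
    recall = float(tp / n_ref) if n_ref > 0 else 0.0
    return 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0


def f_score(detected: Community, reference) -> float:
    """Size-weighted mean over reference classes of the best-match F1."""
    if not detected.clusters:
        raise ValueError("no detected clusters")
    refs = _as_reference_sets(reference)
    total = sum(len(r) for r in refs)
    if total == 0:
        raise ValueError("empty reference")
    acc = 0.0
    for r in refs:
        best = 0.0
        for c in detected.clusters:
            inter = len(c & r)
            if inter == 0:
                continue
            p, q = inter / len(c), inter / len(r)
            best = max(best, 2 * p * q / (p + q))
        acc += len(r) * best
    return acc / total


def composite_score(detected: Community, reference, omega: float = 0.25) -> dict[str, float]:
    """All three scores plus their mean, as a flat dict."""
    p, r, f = f_measure(detected, reference, omega)
    scores = {
        "f_measure": f,
        "precision": p,
        "recall": r,
        "pr_metric": pr_metric(detected, reference),
        "f_score": f_score(detected, reference),
    }
    scores["composite"] = float(
        np.mean([scores["f_measure"], scores["pr_metric"], scores["f_score"]])
    )
    return scores


def composition_table(detected: Community, labels: MetaLabels) -> pd.DataFrame:
    """K × 6 contingency counts of cluster membership by meta-class.

    Overlapping samples are counted in each cluster they belong to; the
    ``dominant`` column names each cluster's most frequent meta-class.
    """
    for z, c in enumerate(detected.clusters):
        for s in c:
            if s not in labels.habitat:
                raise KeyError(f"sample {s!r} in cluster {z} has no meta-labels")
    rows = []
    for z, c in enumerate(detected.clusters):
        counts = {mc: 0 for mc in META_CLASSES}
        for s in c:
            counts[labels.meta_class(s)] += 1
        rows.append(counts)
    table = pd.DataFrame(rows, index=[f"cluster_{z}" for z in range(len(rows))])
    table["dominant"] = table[list(META_CLASSES)].idxmax(axis=1)
    return table


def gender_variation(
    detected: Community, m: SimilarityMatrix, labels: MetaLabels
) -> pd.DataFrame:
    """Mean within-cluster similarity split by gender agreement.

    One row per cluster with columns ``same_gender`` and
    ``opposite_gender`` (means over unordered within-cluster pairs); a
    side with no pairs is reported as NaN, never 0.
    """
    rows = []
    for z, c in enumerate(detected.clusters):
        same, opp = [], []
        members = sorted(c)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sim = m.values[m.index_of(a), m.index_of(b)]
                (same if labels.gender[a] == labels.gender[b] else opp).append(sim)
        rows.append(
            {
                "cluster": f"cluster_{z}",
                "size": len(c),
                "same_gender": float(np.mean(same)) if same else np.nan,
                "opposite_gender": float(np.mean(opp)) if opp else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
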