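"""Consensus matrix W: co-clustering frequency across base results.

W_ij is the number of base clustering results that place samples i and j
in the same cluster, divided by the total number of base results. A NOISE
(unassigned) sample co-clusters with nobody in that partition — noise is
"no assignment", not a shared cluster. The diagonal is fixed at 1 so W is
a valid similarity matrix for the factorization stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .base_clustering import NOISE, Partition
from .similarity import SimilarityMatrix

__all__ = ["build_consensus"]


def build_consensus(partitions: Sequence[Partition]) -> SimilarityMatrix:
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    ids = partitions[0].sample_ids
    for p in partitions[1:]:
        if p.sample_ids != ids:
            raise ValueError("partitions cover different sample-id lists")
    n = len(ids)
    counts = np.zeros((n, n))
    for p in partitions:
        lab = p.labels
        assigned = lab != NOISE
        co = (lab[:, None] == lab[None, :]) & assigned[:, None] & assigned[None, :]
        counts += co
    W = counts / len(partitions)
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(list(ids), W)
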