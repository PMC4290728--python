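"""Top-level pipeline: similarity → ensemble → consensus → NMF → report.

Runs the whole detection chain from either (abundance table + tree) or a
precomputed similarity matrix, writing every intermediate artifact and
logging each stage with its parameters. Fully deterministic given the
seed in the configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io
from .base_clustering import EnsembleConfig, generate_ensemble
from .consensus import build_consensus
from .evaluation import (
    MetaLabels,
    composite_score,
    composition_table,
    gender_variation,
    reference_clusters,
)
from .similarity import (
    DEFAULT_DECAY,
    AbundanceProfile,
    PhyloTree,
    SimilarityMatrix,
    similarity_matrix,
    threshold_network,
)
from .symnmf import Community, factorize, init_from_partition, threshold_membership

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one detection run, auditable as a single record."""

    abundance: Optional[str] = None
    tree: Optional[str] = None
    similarity: Optional[str] = None
    labels: Optional[str] = None
    out_dir: Optional[str] = None
    decay: float = DEFAULT_DECAY
    workers: int = 1
    edge_threshold: float = 0.7
    k_values: tuple[int, ...] = (6, 7, 8, 9, 10)
    ensemble_seeds: tuple[int, ...] = (0, 1, 2)
    eps_values: tuple[float, ...] = (0.1, 0.2, 0.3)
    min_pts: int = 4
    K: int = 6
    beta: float = 1.0
    tau: float = 0.5
    rho: float = 1e-6
    max_iter: int = 200
    restarts: int = 10
    seed: int = 0
    init_partition: Optional[str] = None
    omega: float = 0.25

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML or JSON config; keyword arguments override file values."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("k_values", "ensemble_seeds", "eps_values"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 <= self.edge_threshold <= 1:
            raise ValueError("edge_threshold must lie in [0, 1]")
        if not 0 <= self.decay <= 1:
            raise ValueError("decay must lie in [0, 1]")
        if self.tau <= 0 or self.rho <= 0 or self.beta < 0:
            raise ValueError("tau and rho must be positive, beta nonnegative")
        if self.max_iter < 1 or self.restarts < 1 or self.workers < 1:
            raise ValueError("max_iter, restarts and workers must be positive")


@dataclass
class PipelineResult:
    community: Community
    consensus: SimilarityMatrix
    similarity: SimilarityMatrix
    H: np.ndarray
    report: dict = field(default_factory=dict)


def run_pipeline(
    cfg: PipelineConfig,
    profiles: Optional[Sequence[AbundanceProfile]] = None,
    tree: Optional[PhyloTree] = None,
    sim: Optional[SimilarityMatrix] = None,
    labels: Optional[MetaLabels] = None,
) -> PipelineResult:
    """Execute every stage; in-memory inputs override configured paths."""
    cfg.validate()
    if sim is None and cfg.similarity is None:
        if (profiles is None and cfg.abundance is None) or (tree is None and cfg.tree is None):
            raise ValueError("provide either a similarity matrix or abundance + tree")
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0):
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    try:
        if sim is None:
            if cfg.similarity is not None:
                sim = io.read_similarity(cfg.similarity)
            else:
                t0 = stage("similarity")
                if profiles is None:
                    profiles = io.read_abundance(cfg.abundance)
                if tree is None:
                    tree = PhyloTree.from_newick(cfg.tree)
                sim = similarity_matrix(
                    profiles, tree, decay=cfg.decay, workers=cfg.workers, normalize=True
                )
                done("similarity", t0)
        if labels is None and cfg.labels is not None:
            labels = io.read_labels(cfg.labels)
        if out_dir:
            io.write_similarity(sim, out_dir / "similarity.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'similarity' failed: {exc}") from exc

    try:
        t0 = stage("threshold")
        net = threshold_network(sim, cfg.edge_threshold)
        done("threshold", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'threshold' failed: {exc}") from exc

    try:
        t0 = stage("ensemble")
        ecfg = EnsembleConfig.default(
            k_values=[k for k in cfg.k_values if 2 <= k <= net.n],
            seeds=cfg.ensemble_seeds,
            eps_values=cfg.eps_values,
            min_pts=cfg.min_pts,
        )
        partitions = generate_ensemble(net, ecfg)
        if out_dir:
            io.write_ensemble(partitions, out_dir / "base")
        done("ensemble", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ensemble' failed: {exc}") from exc

    try:
        t0 = stage("consensus")
        W = build_consensus(partitions)
        if out_dir:
            io.write_similarity(W, out_dir / "consensus.tsv")
        done("consensus", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'consensus' failed: {exc}") from exc

    try:
        t0 = stage("factorize")
        init = None
        if cfg.init_partition is not None:
            init = init_from_partition(io.read_partition(cfg.init_partition), cfg.K)
        res = factorize(
            W,
            K=cfg.K,
            beta=cfg.beta,
            rho=cfg.rho,
            max_iter=cfg.max_iter,
            restarts=cfg.restarts,
            seed=cfg.seed,
            init=init,
        )
        logger.info(
            "factorize: restart %d chosen, cost %.6g, %d iterations, converged=%s",
            res.restart_index,
            res.cost,
            res.iterations,
            res.converged,
        )
        community = threshold_membership(
            res.H, W.sample_ids, tau=cfg.tau, row_normalize=True
        )
        if out_dir:
            io.write_community(community, out_dir / "clusters.tsv")
        done("factorize", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'factorize' failed: {exc}") from exc

    report: dict = {
        "config": asdict(cfg),
        "n_samples": sim.n,
        "n_base_results": len(partitions),
        "n_clusters": community.n_clusters,
        "n_unassigned": len(community.unassigned),
        "factorization": {
            "cost": res.cost,
            "iterations": res.iterations,
            "converged": res.converged,
            "restart_index": res.restart_index,
        },
    }
    if labels is not None:
        try:
            t0 = stage("evaluate")
            missing = set(sim.sample_ids) - set(labels.sample_ids)
            if missing:
                raise ValueError(f"samples without meta-labels: {sorted(missing)[:5]}")
            ref = reference_clusters(labels)
            report["scores"] = composite_score(community, ref, omega=cfg.omega)
            report["composition"] = json.loads(
                composition_table(community, labels).to_json(orient="index")
            )
            report["gender_variation"] = json.loads(
                gender_variation(community, sim, labels).to_json(orient="index")
            )
            done("evaluate", t0)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'evaluate' failed: {exc}") from exc
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return PipelineResult(community, W, sim, res.H, report)
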