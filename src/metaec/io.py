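"""Readers and writers for the pipeline's plain-text formats.

All artifacts are TSV (plus Newick for trees and JSON for manifests and
reports): an abundance table has samples as rows and taxon columns; a
similarity/consensus matrix is a full square TSV with a header row and
index column of sample ids; a partition is ``sample_id<TAB>cluster_id``
with ``-1`` marking noise/unassigned; a meta-label table has columns
``sample_id, habitat, gender``. Every writer's output round-trips
through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .base_clustering import NOISE, Partition
from .evaluation import MetaLabels
from .similarity import AbundanceProfile, SimilarityMatrix
from .symnmf import Community

__all__ = [
    "read_similarity",
    "write_similarity",
    "read_abundance",
    "write_abundance",
    "read_labels",
    "write_labels",
    "read_partition",
    "write_partition",
    "read_community",
    "write_community",
    "write_ensemble",
    "read_ensemble",
]


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column sample ids differ (matrix must be square)")
    vals = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(f"{path}: non-finite value at row {ids[i]!r}, column {ids[j]!r}")
    if not np.allclose(vals, vals.T, atol=1e-9, rtol=0):
        i, j = np.argwhere(np.abs(vals - vals.T) > 1e-9)[0]
        raise ValueError(f"{path}: asymmetric at row {ids[i]!r}, column {ids[j]!r}")
    if vals.min() < 0 or vals.max() > 1:
        i, j = np.argwhere((vals < 0) | (vals > 1))[0]
        raise ValueError(f"{path}: value outside [0,1] at row {ids[i]!r}, column {ids[j]!r}")
    return SimilarityMatrix(ids, (vals + vals.T) / 2)


def write_similarity(m: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.sample_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_abundance(path: str | Path, normalize: bool = True) -> list[AbundanceProfile]:
    """Rows = samples, header = taxon names; L1-normalized on load by default."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    out = []
    for sid, row in df.iterrows():
        p = AbundanceProfile(str(sid), {str(t): float(v) for t, v in row.items()})
        if normalize and not p.is_normalized:
            p = p.normalize()
        out.append(p)
    return out


def write_abundance(profiles: Sequence[AbundanceProfile], path: str | Path) -> None:
    taxa = sorted({t for p in profiles for t in p.abundance})
    df = pd.DataFrame(
        [[p.abundance.get(t, 0.0) for t in taxa] for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=taxa,
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path: str | Path) -> MetaLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "habitat", "gender"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return MetaLabels(
        dict(zip(df["sample_id"], df["habitat"])),
        dict(zip(df["sample_id"], df["gender"])),
    )


def write_labels(labels: MetaLabels, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": labels.sample_ids,
            "habitat": [labels.habitat[s] for s in labels.sample_ids],
            "gender": [labels.gender[s] for s in labels.sample_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cluster_id": int})
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return Partition(df["sample_id"].tolist(), df["cluster_id"].to_numpy())


def write_partition(p: Partition, path: str | Path) -> None:
    pd.DataFrame({"sample_id": p.sample_ids, "cluster_id": p.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_ensemble(partitions: Sequence[Partition], out_dir: str | Path) -> None:
    """One partition TSV per base result plus a JSON provenance manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, p in enumerate(partitions):
        name = f"partition_{i:03d}.tsv"
        write_partition(p, out_dir / name)
        manifest.append({"file": name, **p.provenance})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_ensemble(out_dir: str | Path) -> list[Partition]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    out = []
    for rec in manifest:
        p = read_partition(out_dir / rec["file"])
        p.provenance = {k: v for k, v in rec.items() if k != "file"}
        out.append(p)
    return out


def write_community(c: Community, path: str | Path) -> None:
    """Repeated rows for overlapping membership; -1 for unassigned."""
    rows = []
    for z, cluster in enumerate(c.clusters):
        for s in sorted(cluster):
            rows.append((s, z))
    for s in sorted(c.unassigned):
        rows.append((s, NOISE))
    pd.DataFrame(rows, columns=["sample_id", "cluster_id"]).to_csv(path, sep="\t", index=False)


def read_community(path: str | Path, sample_ids: Sequence[str] | None = None) -> Community:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cluster_id": int})
    ids = list(dict.fromkeys(df["sample_id"])) if sample_ids is None else [str(s) for s in sample_ids]
    k = df.loc[df["cluster_id"] != NOISE, "cluster_id"].max()
    clusters = [
        set(df.loc[df["cluster_id"] == z, "sample_id"]) for z in range(int(k) + 1 if pd.notna(k) else 0)
    ]
    clusters = [c for c in clusters if c]
    unassigned = set(df.loc[df["cluster_id"] == NOISE, "sample_id"])
    return Community(ids, clusters, unassigned)
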