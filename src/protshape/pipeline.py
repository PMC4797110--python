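"""End-to-end comparison, batch similarity, nearest-model search and clustering.

The unit of work is: read -> clean -> orient -> descriptor -> grey relation.
Descriptors are cached per model within a batch, and each model's K-means seed
is derived from one global seed offset by a hash of the model name, so adding
a model to a batch never changes the other models' descriptors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .descriptor import DescriptorConfig, FeatureMatrix, compute_descriptor, _with_seed
from .features import SGFConfig
from .grey import matrix_grey_relation
from .mesh import TriangleMesh, clean_mesh, orient_outward, read_mesh

MESH_SUFFIXES = (".off", ".ply", ".obj")


def model_seed(base_seed: int, name: str) -> int:
    """Per-model seed: global seed offset by a stable hash of the model name."""
    return int((base_seed + zlib.crc32(name.encode("utf-8"))) % 2**31)


def prepare_mesh(source, name: str | None = None) -> TriangleMesh:
    """Load (if a path), clean and consistently orient a mesh."""
    mesh = read_mesh(source) if not isinstance(source, TriangleMesh) else source
    if name:
        mesh = TriangleMesh(mesh.vertices, mesh.faces, name=name)
    return orient_outward(clean_mesh(mesh))


def _descriptor_for(mesh: TriangleMesh, sgf_cfg: SGFConfig, cfg: DescriptorConfig,
                    base_seed: int) -> FeatureMatrix:
    return compute_descriptor(mesh, sgf_cfg, _with_seed(cfg, model_seed(base_seed, mesh.name)))


def compare(mesh_a, mesh_b, sgf_cfg: SGFConfig | None = None,
            cfg: DescriptorConfig | None = None, seed: int = 0) -> float:
    """Grey relation degree between two meshes' feature-matrix descriptors."""
    sgf_cfg = sgf_cfg or SGFConfig()
    cfg = cfg or DescriptorConfig()
    a = prepare_mesh(mesh_a)
    b = prepare_mesh(mesh_b)
    da = _descriptor_for(a, sgf_cfg, cfg, seed)
    db = _descriptor_for(b, sgf_cfg, cfg, seed)
    return matrix_grey_relation(da.M, db.M).eta


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of grey relation degrees with unit diagonal."""

    labels: list[str]
    S: np.ndarray

    def to_csv(self, path, decimals: int = 4) -> None:
        with open(path, "w") as fh:
            fh.write("model," + ",".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.S):
                fh.write(lab + "," + ",".join(f"{v:.{decimals}f}" for v in row) + "\n")


@dataclass
class Dendrogram:
    """Average-linkage merge history over model labels."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height: float) -> str:
            height = node.dist
            length = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, height)
            right = rec(node.right, height)
            return f"({left},{right}):{length:.6g}"

        root = tree
        inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
        return f"({inner}):0;"


def _collect_meshes(source, sgf_cfg, cfg, seed, skip_bad=False):
    """Load and prepare meshes from a directory, list of paths, or list of meshes."""
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(p for p in Path(source).iterdir()
                       if p.suffix.lower() in MESH_SUFFIXES)
    else:
        paths = list(source)
    meshes, failures = [], []
    for p in paths:
        if isinstance(p, TriangleMesh):
            meshes.append(prepare_mesh(p))
            continue
        try:
            meshes.append(prepare_mesh(p))
        except Exception as exc:
            failures.append((str(p), str(exc)))
    if failures and not skip_bad:
        detail = "; ".join(f"{p}: {e}" for p, e in failures)
        raise IOError(f"failed to read {len(failures)} mesh(es): {detail}")
    return meshes


def all_vs_all(source, sgf_cfg: SGFConfig | None = None,
               cfg: DescriptorConfig | None = None, seed: int = 0,
               skip_bad: bool = False) -> SimilarityMatrix:
    """Pairwise grey relation degrees; each descriptor is computed exactly once."""
    sgf_cfg = sgf_cfg or SGFConfig()
    cfg = cfg or DescriptorConfig()
    meshes = _collect_meshes(source, sgf_cfg, cfg, seed, skip_bad)
    if len(meshes) < 2:
        raise ValueError("need at least 2 meshes for all-vs-all comparison")
    descs = [_descriptor_for(m, sgf_cfg, cfg, seed) for m in meshes]
    n = len(descs)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = matrix_grey_relation(descs[i].M, descs[j].M).eta
    return SimilarityMatrix([m.name for m in meshes], S)


def rank_query(query, library, sgf_cfg: SGFConfig | None = None,
               cfg: DescriptorConfig | None = None, seed: int = 0,
               skip_bad: bool = False) -> list[tuple[str, float]]:
    """Models of a library ranked by similarity to the query (descending eta).

    Ties break by label so the ranking is stable.
    """
    sgf_cfg = sgf_cfg or SGFConfig()
    cfg = cfg or DescriptorConfig()
    lib = _collect_meshes(library, sgf_cfg, cfg, seed, skip_bad)
    if not lib:
        raise ValueError("empty mesh library")
    q = prepare_mesh(query)
    dq = _descriptor_for(q, sgf_cfg, cfg, seed)
    scored = []
    for m in lib:
        d = _descriptor_for(m, sgf_cfg, cfg, seed)
        scored.append((m.name, matrix_grey_relation(dq.M, d.M).eta))
    return sorted(scored, key=lambda kv: (-kv[1], kv[0]))


def average_linkage(sim: SimilarityMatrix) -> Dendrogram:
    """UPGMA dendrogram on the dissimilarity d = 1 - eta.

    Average-linkage heights are monotone non-decreasing along the merge
    sequence, and serialise to Newick with merge heights as branch heights.
    """
    if len(sim.labels) < 2:
        raise ValueError("need at least 2 models to cluster")
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(list(sim.labels), Z)
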