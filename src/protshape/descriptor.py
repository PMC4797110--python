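"""K x K feature-matrix descriptor built from 1-D K-means condensations of SI and SGF.

Each per-vertex field is condensed to K cluster means (K = 48 by default):
vector T for the shape index and P for the salient geometric feature.  The
descriptor is the K x K symmetric positive semi-definite matrix

    M = T T^t + P P^t        (rank <= 2)

i.e. Q^t Q for Q the 2 x K stack of the two vectors.  Cluster means are sorted
ascending by default, which makes the descriptor canonical: K-means labels
carry no meaning across runs, and sorting removes that arbitrariness so two
descriptors can be compared entry-wise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import kmeans1d as _kmeans1d
from .curvature import curvature_field
from .features import SGFConfig, shape_index, sgf_field, DEFAULT_UMBILIC_TOL
from .mesh import TriangleMesh


@dataclass
class DescriptorConfig:
    K: int = 48
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-8
    sort_clusters: bool = True
    exclude_boundary: bool = True
    umbilic_tol: float = DEFAULT_UMBILIC_TOL
    n_init: int = 3       # uniform + as many D^2-weighted restarts
    ils_rounds: int = 8   # kick/descend cycles after the restarts

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class FeatureVector:
    """K cluster means of one per-vertex channel (SI or SGF)."""

    values: np.ndarray
    channel: str  # "SI" or "SGF"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


@dataclass
class FeatureMatrix:
    """The K x K descriptor plus the provenance needed to reproduce it."""

    M: np.ndarray
    T: FeatureVector
    P: FeatureVector
    name: str = ""
    seed: int | None = None
    config: dict = field(default_factory=dict)
    mesh_hash: str = ""

    @property
    def K(self) -> int:
        return len(self.T.values)

    # -- JSON cache -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "K": self.K,
            "seed": self.seed,
            "config": self.config,
            "mesh_hash": self.mesh_hash,
            "T": self.T.values.tolist(),
            "P": self.P.values.tolist(),
            "M": self.M.ravel().tolist(),  # row-major
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "FeatureMatrix":
        d = json.loads(Path(path).read_text())
        K = int(d["K"])
        return cls(
            M=np.asarray(d["M"], dtype=np.float64).reshape(K, K),
            T=FeatureVector(d["T"], "SI"),
            P=FeatureVector(d["P"], "SGF"),
            name=d.get("name", ""),
            seed=d.get("seed"),
            config=d.get("config", {}),
            mesh_hash=d.get("mesh_hash", ""),
        )


def kmeans_1d(values, cfg: DescriptorConfig) -> np.ndarray:
    """K cluster means of a scalar field, by seeded restarted Lloyd + refinement.

    Initial centers are data points sampled with ``cfg.seed`` (uniform and
    D^2-weighted draws); Lloyd assignment breaks ties toward the lower-indexed
    center and re-seeds empty clusters with the farthest point.  A merge-split
    descent on the sorted-interval representation then polishes each run to
    near-optimal within-cluster sum of squares (plain Lloyd routinely stalls
    well above it at large K).  Returns the K means in ascending order;
    deterministic given (values, cfg).
    """
    return _kmeans1d.solve(values, cfg.K, cfg.seed, max_iter=cfg.max_iter,
                           tol=cfg.tol, n_init=cfg.n_init,
                           ils_rounds=cfg.ils_rounds)


def feature_vector(values, channel: str, cfg: DescriptorConfig) -> FeatureVector:
    """Condense one per-vertex field to its K cluster means (sorted by default)."""
    means = kmeans_1d(values, cfg)
    if cfg.sort_clusters:
        means = np.sort(means)
    return FeatureVector(means, channel)


def build_feature_matrix(T: FeatureVector, P: FeatureVector) -> FeatureMatrix:
    """M[a, b] = T[a] T[b] + P[a] P[b]: symmetric, PSD, rank <= 2."""
    t, p = T.values, P.values
    if len(t) != len(p):
        raise ValueError("T and P must have the same length K")
    M = np.outer(t, t) + np.outer(p, p)
    return FeatureMatrix(M=M, T=T, P=P)


def _mesh_hash(mesh: TriangleMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]


def compute_descriptor(
    mesh: TriangleMesh,
    sgf_cfg: SGFConfig | None = None,
    cfg: DescriptorConfig | None = None,
) -> FeatureMatrix:
    """Full chain: curvature -> SI -> SGF -> (T, P) -> K x K feature matrix.

    Deterministic given (mesh, configs, seed).  The SI and SGF channels are
    clustered independently, each with its own child stream of ``cfg.seed``.
    Boundary vertices are excluded from both channels by default (their
    curvature estimates are biased).
    """
    sgf_cfg = sgf_cfg or SGFConfig()
    cfg = cfg or DescriptorConfig()
    curv = curvature_field(mesh)
    si = shape_index(curv, umbilic_tol=cfg.umbilic_tol)
    sgf = sgf_field(mesh, si, sgf_cfg)
    keep = ~si.boundary if cfg.exclude_boundary else np.ones(mesh.n_vertices, dtype=bool)
    si_vals = si.si[keep]
    sgf_vals = sgf.sgf[keep]
    if len(si_vals) < cfg.K:
        raise ValueError(
            f"mesh {mesh.name!r} has only {len(si_vals)} usable vertices for K={cfg.K}"
        )
    seed_si, seed_sgf = [int(s.generate_state(1)[0] % 2**31)
                         for s in np.random.SeedSequence(cfg.seed).spawn(2)]
    T = feature_vector(si_vals, "SI", _with_seed(cfg, seed_si))
    P = feature_vector(sgf_vals, "SGF", _with_seed(cfg, seed_sgf))
    fm = build_feature_matrix(T, P)
    fm.name = mesh.name
    fm.seed = cfg.seed
    fm.config = {"descriptor": asdict(cfg), "sgf": asdict(sgf_cfg)}
    fm.mesh_hash = _mesh_hash(mesh)
    return fm


def _with_seed(cfg: DescriptorConfig, seed: int) -> DescriptorConfig:
    return DescriptorConfig(
        K=cfg.K, seed=seed, max_iter=cfg.max_iter, tol=cfg.tol,
        sort_clusters=cfg.sort_clusters, exclude_boundary=cfg.exclude_boundary,
        umbilic_tol=cfg.umbilic_tol, n_init=cfg.n_init, ils_rounds=cfg.ils_rounds,
    )
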