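"""Discrete per-vertex curvature: Gaussian (angle deficit), mean (edge dihedrals),
and the principal curvatures recovered from the pair.

Sign convention
---------------
Mean curvature carries the *convex-negative* convention: a closed convex
surface with outward-facing winding gets kM < 0 (unit sphere -> kM = -1 in the
refinement limit).  This calibration is what makes the shape-index formula
``SI = -(2/pi) arctan((k1+k2)/(k1-k2))`` assign +1 to convex caps and -1 to
concave cups, and it is pinned down by an explicit unit-sphere test.

Vertex areas here are Meyer-style mixed (Voronoi with obtuse correction)
areas: pointwise curvature accuracy on smooth meshes depends on the area
weights matching the angle-deficit/dihedral numerators, and mixed areas keep
the kM^2 - kG discriminant non-negative on well-shaped meshes where the
simpler one-third-of-incident-faces weighting does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh


@dataclass
class CurvatureField:
    """Per-vertex kG, kM and principal curvatures k1 >= k2.

    ``clamped`` marks vertices where the discriminant kM^2 - kG was negative
    (numerically inconsistent discrete estimates, treated as umbilic);
    ``boundary`` marks vertices on open edges, whose estimates are biased.
    """

    kG: np.ndarray
    kM: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    clamped: np.ndarray
    boundary: np.ndarray


def _corner_angles(mesh: TriangleMesh) -> np.ndarray:
    """(m, 3) interior angle at each face corner."""
    tri = mesh.vertices[mesh.faces]
    ang = np.empty((len(tri), 3))
    for c in range(3):
        u = tri[:, (c + 1) % 3] - tri[:, c]
        v = tri[:, (c + 2) % 3] - tri[:, c]
        ang[:, c] = np.arctan2(
            np.linalg.norm(np.cross(u, v), axis=1), np.einsum("ij,ij->i", u, v)
        )
    return ang


def mixed_vertex_area(mesh: TriangleMesh) -> np.ndarray:
    """Meyer mixed (Voronoi / obtuse-corrected) vertex areas; sums to total area."""
    tri = mesh.vertices[mesh.faces]
    ang = _corner_angles(mesh)
    fa = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    A = np.zeros(mesh.n_vertices)
    obtuse_any = (ang > np.pi / 2).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = 1.0 / np.tan(ang)
    for c in range(3):
        nxt, prv = (c + 1) % 3, (c + 2) % 3
        e_nxt = tri[:, nxt] - tri[:, c]      # opposite corner prv
        e_prv = tri[:, prv] - tri[:, c]      # opposite corner nxt
        voronoi = (
            np.einsum("ij,ij->i", e_prv, e_prv) * cot[:, nxt]
            + np.einsum("ij,ij->i", e_nxt, e_nxt) * cot[:, prv]
        ) / 8.0
        contrib = np.where(
            ~obtuse_any, voronoi, np.where(ang[:, c] > np.pi / 2, fa / 2.0, fa / 4.0)
        )
        np.add.at(A, mesh.faces[:, c], contrib)
    return A


def angle_deficit(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex angle deficit: 2*pi - sum(angles) interior, pi - sum on the boundary.

    Summed over a closed mesh this equals 2*pi*chi exactly (discrete
    Gauss-Bonnet), independent of any area weighting.
    """
    ang = _corner_angles(mesh)
    total = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(total, mesh.faces[:, c], ang[:, c])
    full = np.where(mesh.boundary_vertices(), np.pi, 2 * np.pi)
    return full - total


def gaussian_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Discrete Gaussian curvature: angle deficit divided by the mixed vertex area."""
    A = mixed_vertex_area(mesh)
    if np.any(A <= 0):
        raise ValueError("vertex with no incident faces or degenerate area; clean the mesh first")
    return angle_deficit(mesh) / A


def mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Discrete mean curvature from edge lengths and signed dihedral angles.

    kM_i = -(1 / (4 A_i)) * sum over incident interior edges of len(e) * beta(e),
    with beta(e) the signed dihedral (positive where the edge is convex w.r.t.
    outward normals).  The leading minus sign is the convex-negative
    calibration (see module docstring).  Boundary edges contribute zero.
    """
    A = mixed_vertex_area(mesh)
    if np.any(A <= 0):
        raise ValueError("vertex with no incident faces or degenerate area; clean the mesh first")
    edges, counts, edge_faces, edge_dirs = mesh._edges()
    unit, _ = mesh.face_normals_areas()
    interior = counts == 2
    d1 = edge_dirs[interior, 0]                  # directed traversal in the first face
    f1 = edge_faces[interior, 0]
    f2 = edge_faces[interior, 1]
    ev = mesh.vertices[d1[:, 1]] - mesh.vertices[d1[:, 0]]
    elen = np.linalg.norm(ev, axis=1)
    ehat = ev / np.where(elen == 0, 1, elen)[:, None]
    n1, n2 = unit[f1], unit[f2]
    beta = np.arctan2(np.einsum("ij,ij->i", np.cross(n1, n2), ehat),
                      np.einsum("ij,ij->i", n1, n2))
    contrib = elen * beta
    H = np.zeros(mesh.n_vertices)
    np.add.at(H, d1[:, 0], contrib)
    np.add.at(H, d1[:, 1], contrib)
    return -H / (4.0 * A)


def principal_from_GM(kG: np.ndarray, kM: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k1 = kM + sqrt(kM^2 - kG), k2 = kM - sqrt(kM^2 - kG), clamping negatives.

    A negative discriminant means the two discrete estimates are mutually
    inconsistent; it is clamped to zero (umbilic) and flagged.
    Always returns k1 >= k2 with k1 + k2 = 2 kM exactly.
    """
    kG = np.asarray(kG, dtype=np.float64)
    kM = np.asarray(kM, dtype=np.float64)
    if kG.shape != kM.shape:
        raise ValueError("kG and kM must be aligned")
    disc = kM * kM - kG
    clamped = disc < 0
    root = np.sqrt(np.maximum(disc, 0.0))
    return kM + root, kM - root, clamped


def curvature_field(mesh: TriangleMesh) -> CurvatureField:
    """Full per-vertex curvature field of a clean, consistently oriented mesh."""
    kG = gaussian_curvature(mesh)
    kM = mean_curvature(mesh)
    k1, k2, clamped = principal_from_GM(kG, kM)
    return CurvatureField(kG, kM, k1, k2, clamped, mesh.boundary_vertices())
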