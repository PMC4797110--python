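"""Deterministic synthetic meshes with analytic curvature oracles.

Spheres, tori and saddle patches have closed-form Gaussian and mean curvature,
so every downstream stage (discrete curvature, shape index, descriptors,
similarity) can be validated without any protein data.  The noise and blobby
deformers produce controlled perturbations and distinct lumpy shapes for
robustness and retrieval tests; all randomness flows through explicit seeds.

Oracle sign convention: ``kM_signed`` follows the convex-negative convention
used by the curvature module (outward-oriented convex surface => kM < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

from .mesh import TriangleMesh

SIGN_CONVENTION = "convex-negative"


@dataclass
class AnalyticOracle:
    """Exact per-vertex curvatures from the closed-form surface equations."""

    kG: np.ndarray                     # Gaussian curvature, 1/length^2
    kM_signed: np.ndarray              # mean curvature under convex-negative convention
    sign_convention: str = SIGN_CONVENTION

    @property
    def kM_magnitude(self) -> np.ndarray:
        return np.abs(self.kM_signed)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> tuple[TriangleMesh, AnalyticOracle]:
    """Icosahedron subdivided and projected to a sphere: 10*4^s + 2 vertices.

    Oracle: kG = 1/r^2, kM = -1/r everywhere.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = TriangleMesh(np.asarray(tm.vertices, dtype=np.float64),
                        np.asarray(tm.faces, dtype=np.int64),
                        name=f"icosphere_r{radius:g}_s{subdivisions}")
    n = mesh.n_vertices
    oracle = AnalyticOracle(np.full(n, 1.0 / radius**2), np.full(n, -1.0 / radius))
    return mesh, oracle


def torus(R: float, r: float, nu: int = 48, nv: int = 24) -> tuple[TriangleMesh, AnalyticOracle]:
    """Torus of revolution (major radius R, tube radius r) on a regular grid.

    With tube angle v (v = 0 on the outer equator):
    kG = cos v / (r (R + r cos v)),  |kM| = (R + 2 r cos v) / (2 r (R + r cos v)).
    """
    if not (R > r > 0):
        raise ValueError("require R > r > 0")
    if nu < 3 or nv < 3:
        raise ValueError("require nu, nv >= 3")
    u = 2 * np.pi * np.arange(nu) / nu           # around the main ring
    v = 2 * np.pi * np.arange(nv) / nv           # around the tube
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (R + r * np.cos(vv)) * np.cos(uu)
    y = (R + r * np.cos(vv)) * np.sin(uu)
    z = r * np.sin(vv)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    idx = np.arange(nu * nv).reshape(nu, nv)
    i00 = idx
    i10 = np.roll(idx, -1, axis=0)
    i01 = np.roll(idx, -1, axis=1)
    i11 = np.roll(np.roll(idx, -1, axis=0), -1, axis=1)
    # windings chosen so the surface is outward-oriented as built
    f1 = np.stack([i00, i10, i01], axis=-1).reshape(-1, 3)
    f2 = np.stack([i10, i11, i01], axis=-1).reshape(-1, 3)
    mesh = TriangleMesh(verts, np.concatenate([f1, f2]), name=f"torus_R{R:g}_r{r:g}")
    cv = np.cos(vv).ravel()
    kG = cv / (r * (R + r * cv))
    kM = -(R + 2 * r * cv) / (2 * r * (R + r * cv))
    return mesh, AnalyticOracle(kG, kM)


def saddle_patch(extent: float = 1.0, n: int = 41) -> tuple[TriangleMesh, AnalyticOracle]:
    """Open saddle z = x^2 - y^2 over [-extent, extent]^2 on an n x n grid.

    Exercises the SI = 0 case: at the origin k1 = -k2, so kM = 0 and kG = -4.
    The oracle uses the graph-surface curvature formulas
    kG = f_xx f_yy - f_xy^2 over (1 + |grad f|^2)^2 and
    2 kM = div(grad f / sqrt(1 + |grad f|^2)).
    """
    if n < 2:
        raise ValueError("need n >= 2 grid points per side")
    t = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(t, t, indexing="ij")
    zz = xx**2 - yy**2
    verts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    idx = np.arange(n * n).reshape(n, n)
    i00 = idx[:-1, :-1].ravel()
    i10 = idx[1:, :-1].ravel()
    i01 = idx[:-1, 1:].ravel()
    i11 = idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.stack([i00, i10, i11], axis=1),
        np.stack([i00, i11, i01], axis=1),
    ])
    mesh = TriangleMesh(verts, faces, name=f"saddle_e{extent:g}_n{n}")
    x, y = xx.ravel(), yy.ravel()
    fx, fy = 2 * x, -2 * y
    fxx, fyy, fxy = 2.0, -2.0, 0.0
    g = 1 + fx**2 + fy**2
    kG = (fxx * fyy - fxy**2) / g**2
    # upward-normal mean curvature of a graph; sign convention is moot here
    # (the saddle is used for its kM = 0 center and negative kG)
    kM = ((1 + fy**2) * fxx - 2 * fx * fy * fxy + (1 + fx**2) * fyy) / (2 * g**1.5)
    return mesh, AnalyticOracle(kG, kM)


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    unit, areas = mesh.face_normals_areas()
    vn = np.zeros_like(mesh.vertices)
    np.add.at(vn, mesh.faces.ravel(), np.repeat(unit * areas[:, None], 3, axis=0))
    nrm = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.where(nrm == 0, 1, nrm)


def add_vertex_noise(mesh: TriangleMesh, sigma: float, seed: int) -> TriangleMesh:
    """Displace each vertex along its normal by N(0, sigma^2); seed-deterministic.

    Normal-direction (rather than isotropic) noise preserves topology at small
    sigma.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), name=mesh.name)
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=mesh.n_vertices)
    verts = mesh.vertices + disp[:, None] * _vertex_normals(mesh)
    return TriangleMesh(verts, mesh.faces.copy(), name=f"{mesh.name}_noise{sigma:g}")


def blobby_deform(mesh: TriangleMesh, amplitude: float, frequency: int = 4,
                  seed: int = 0) -> TriangleMesh:
    """Smooth random radial deformation producing distinct lumpy closed shapes.

    Each vertex p moves to p * (1 + amplitude * f(p/|p|)) about the centroid,
    where f is a seed-determined low-order smooth angular function normalised
    to [-1, 1].  amplitude = 0 is the identity.
    """
    if amplitude == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), name=mesh.name)
    rng = np.random.default_rng(seed)
    center = mesh.vertices.mean(axis=0)
    rel = mesh.vertices - center
    radii = np.linalg.norm(rel, axis=1)
    unit = rel / np.where(radii == 0, 1, radii)[:, None]
    f = np.zeros(mesh.n_vertices)
    for order in range(1, frequency + 1):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        c = rng.normal()
        f += c * (unit @ d) ** order
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    verts = center + rel * (1 + amplitude * f)[:, None]
    return TriangleMesh(verts, mesh.faces.copy(),
                        name=f"{mesh.name}_blob{amplitude:g}s{seed}")
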