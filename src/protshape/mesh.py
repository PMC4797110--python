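"""Triangle-mesh container, I/O (OFF / PLY / OBJ), cleaning and consistent orientation.

Molecular-surface meshes arrive from external surface generators in one of the
three classic polygon formats.  Everything downstream (curvature, shape index)
assumes a clean, consistently outward-oriented triangle mesh, which
:func:`clean_mesh` and :func:`orient_outward` establish.

OFF is parsed by a strict reader of our own (line-numbered errors on corrupt
files); PLY and OBJ go through :mod:`trimesh`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

log = logging.getLogger(__name__)


class MeshIOError(IOError):
    """File could not be read or written."""


class MeshParseError(ValueError):
    """File content does not parse as the claimed format."""


class NonOrientableError(ValueError):
    """A connected component admits no consistent face orientation."""


@dataclass
class TriangleMesh:
    """Vertices and triangular faces of a surface; the universe every field lives on.

    ``vertices`` is ``(n, 3)`` float64 (units arbitrary, typically Angstrom);
    ``faces`` is ``(m, 3)`` int64 with 0-based indices.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- derived geometry -------------------------------------------------

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals and face areas (degenerate faces get a zero normal)."""
        tri = self.vertices[self.faces]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(cr, axis=1)
        areas = 0.5 * nrm
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(nrm[:, None] > 0, cr / np.where(nrm == 0, 1, nrm)[:, None], 0.0)
        return unit, areas

    def signed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive for outward winding)."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bbox_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        return float(np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0)))

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.unique_edges()[0]) + self.n_faces

    # -- topology (computed on demand, cached) ----------------------------

    _edge_cache: tuple | None = field(default=None, repr=False, compare=False)

    def _edges(self):
        """Directed edges, unique undirected edges and their incidence.

        Returns ``(edges, counts, edge_faces, edge_dirs)`` where ``edges`` is
        ``(e, 2)`` sorted vertex pairs, ``counts[e]`` the number of incident
        faces, ``edge_faces`` ``(e, 2)`` face ids (-1 padding) and
        ``edge_dirs`` ``(e, 2, 2)`` the directed (a, b) traversal of the edge
        in each incident face (undefined rows padded with -1).
        """
        if self._edge_cache is not None:
            return self._edge_cache
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        owner = np.tile(np.arange(len(f)), 3)
        und = np.sort(directed, axis=1)
        key = und[:, 0] * (self.n_vertices + 1) + und[:, 1]
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        uniq_mask = np.ones(len(key_s), dtype=bool)
        uniq_mask[1:] = key_s[1:] != key_s[:-1]
        starts = np.flatnonzero(uniq_mask)
        counts = np.diff(np.append(starts, len(key_s)))
        if counts.size and counts.max() > 2:
            bad = order[starts[counts > 2][0]]
            raise ValueError(
                f"non-manifold edge {tuple(und[bad])}: shared by more than 2 faces"
            )
        e = len(starts)
        edges = und[order[starts]]
        edge_faces = np.full((e, 2), -1, dtype=np.int64)
        edge_dirs = np.full((e, 2, 2), -1, dtype=np.int64)
        edge_faces[:, 0] = owner[order[starts]]
        edge_dirs[:, 0] = directed[order[starts]]
        two = counts == 2
        edge_faces[two, 1] = owner[order[starts[two] + 1]]
        edge_dirs[two, 1] = directed[order[starts[two] + 1]]
        object.__setattr__(self, "_edge_cache", (edges, counts, edge_faces, edge_dirs))
        return self._edge_cache

    def unique_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted unique vertex pairs and the number of faces on each."""
        edges, counts, _, _ = self._edges()
        return edges, counts

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices lying on an edge with a single incident face."""
        edges, counts = self.unique_edges()
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[edges[counts == 1].ravel()] = True
        return mask

    def is_closed(self) -> bool:
        _, counts = self.unique_edges()
        return bool(np.all(counts == 2))

    def vertex_adjacency(self) -> list[np.ndarray]:
        """1-ring neighbour ids per vertex."""
        edges, _ = self.unique_edges()
        order = np.argsort(np.concatenate([edges[:, 0], edges[:, 1]]), kind="stable")
        flat = np.concatenate([edges[:, 1], edges[:, 0]])[order]
        heads = np.concatenate([edges[:, 0], edges[:, 1]])[order]
        splits = np.searchsorted(heads, np.arange(1, self.n_vertices))
        return np.split(flat, splits)

    def invalidate_cache(self) -> None:
        object.__setattr__(self, "_edge_cache", None)


# ---------------------------------------------------------------------------
# I/O

_FORMATS = ("off", "ply", "obj")


def _detect_format(path: Path, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format {fmt!r} for {path}")
    return fmt


def _fan_triangulate(poly: list[int]) -> list[tuple[int, int, int]]:
    return [(poly[0], poly[j], poly[j + 1]) for j in range(1, len(poly) - 1)]


def _read_off(path: Path) -> TriangleMesh:
    with open(path, "r") as fh:
        raw = fh.readlines()
    # strip comments / blanks but remember original line numbers
    lines: list[tuple[int, str]] = []
    for i, ln in enumerate(raw, start=1):
        s = ln.split("#", 1)[0].strip()
        if s:
            lines.append((i, s))
    if not lines:
        raise MeshParseError(f"{path}: empty OFF file")
    lno, head = lines[0]
    rest = lines[1:]
    if head.upper().startswith("OFF"):
        tail = head[3:].strip()
        if tail:  # counts on the header line
            rest = [(lno, tail)] + rest
    else:
        raise MeshParseError(f"{path}:{lno}: expected 'OFF' header")
    if not rest:
        raise MeshParseError(f"{path}: missing OFF count line")
    lno, cnt = rest[0]
    parts = cnt.split()
    if len(parts) < 2:
        raise MeshParseError(f"{path}:{lno}: malformed OFF count line {cnt!r}")
    try:
        nv, nf = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise MeshParseError(f"{path}:{lno}: malformed OFF count line {cnt!r}") from exc
    body = rest[1:]
    if len(body) < nv + nf:
        raise MeshParseError(
            f"{path}:{lno}: header promises {nv} vertices and {nf} faces "
            f"but only {len(body)} data lines follow"
        )
    verts = np.empty((nv, 3), dtype=np.float64)
    for k in range(nv):
        lnum, s = body[k]
        p = s.split()
        if len(p) < 3:
            raise MeshParseError(f"{path}:{lnum}: malformed vertex line {s!r}")
        try:
            verts[k] = [float(p[0]), float(p[1]), float(p[2])]
        except ValueError as exc:
            raise MeshParseError(f"{path}:{lnum}: malformed vertex line {s!r}") from exc
    tris: list[tuple[int, int, int]] = []
    for k in range(nf):
        lnum, s = body[nv + k]
        p = s.split()
        try:
            cnt_i = int(p[0])
            idx = [int(x) for x in p[1 : 1 + cnt_i]]
        except (ValueError, IndexError) as exc:
            raise MeshParseError(f"{path}:{lnum}: malformed face line {s!r}") from exc
        if cnt_i < 3 or len(idx) != cnt_i:
            raise MeshParseError(f"{path}:{lnum}: malformed face line {s!r}")
        if any(i < 0 or i >= nv for i in idx):
            raise MeshParseError(f"{path}:{lnum}: face index out of range in {s!r}")
        tris.extend(_fan_triangulate(idx))
    if len(body) > nv + nf:
        lnum, s = body[nv + nf]
        raise MeshParseError(
            f"{path}:{lnum}: {len(body) - nv - nf} extra data line(s) beyond the "
            f"promised {nv} vertices and {nf} faces"
        )
    return TriangleMesh(verts, np.asarray(tris, dtype=np.int64).reshape(-1, 3), name=path.stem)


def read_mesh(path, format: str = "auto") -> TriangleMesh:
    """Read a triangle mesh from an OFF, PLY or OBJ file (no cleaning applied).

    Polygonal faces with more than 3 sides are fan-triangulated from their
    first vertex.  OBJ's 1-based indices are converted to 0-based.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"no such mesh file: {path}")
    fmt = _detect_format(path, format)
    if fmt == "off":
        return _read_off(path)
    try:
        tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshParseError(f"{path}: failed to parse as {fmt.upper()}: {exc}") from exc
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise MeshParseError(f"{path}: no triangles found in {fmt.upper()} file")
    return TriangleMesh(verts, faces, name=path.stem)


def write_mesh(mesh: TriangleMesh, path, format: str = "auto") -> None:
    """Write a mesh to disk; a read_mesh round trip preserves connectivity exactly."""
    if mesh.n_vertices == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "off":
            with open(path, "w") as fh:
                fh.write("OFF\n")
                fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
                for v in mesh.vertices:
                    fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
                for f in mesh.faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        else:
            tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
            tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Cleaning

def clean_mesh(mesh: TriangleMesh, merge_tol: float | None = None) -> TriangleMesh:
    """Merge near-duplicate vertices, drop degenerate/duplicate faces and orphans.

    ``merge_tol`` defaults to 1e-8 x the bounding-box diagonal (scale-free).
    Always returns; removals are reported through the module logger.
    """
    if merge_tol is None:
        merge_tol = 1e-8 * (mesh.bbox_diagonal() or 1.0)
    verts, faces = mesh.vertices, mesh.faces
    # merge vertices by quantised coordinates
    if merge_tol > 0:
        quant = np.round(verts / merge_tol).astype(np.int64)
        _, first, inverse = np.unique(quant, axis=0, return_index=True, return_inverse=True)
        merged = len(verts) - len(first)
        verts = verts[first]
        faces = inverse[faces]
    else:
        merged = 0
    # drop faces with repeated vertices
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    # drop zero-area slivers (distinct but collinear vertices)
    if len(faces):
        tri = verts[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        scale = mesh.bbox_diagonal() or 1.0
        faces = faces[areas > 1e-14 * scale**2]
    # drop duplicate faces (same vertex set)
    if len(faces):
        key = np.sort(faces, axis=1)
        _, keep = np.unique(key, axis=0, return_index=True)
        dup = len(faces) - len(keep)
        faces = faces[np.sort(keep)]
    else:
        dup = 0
    # drop unreferenced vertices
    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    dropped = int((~used).sum())
    verts = verts[used]
    faces = remap[faces]
    if merged or dup or dropped or len(faces) != mesh.n_faces:
        log.info(
            "clean_mesh(%s): merged %d vertices, removed %d degenerate/%d duplicate "
            "faces, dropped %d unreferenced vertices",
            mesh.name or "<unnamed>", merged, mesh.n_faces - len(faces) - dup, dup, dropped,
        )
    return TriangleMesh(verts, faces, name=mesh.name)


# ---------------------------------------------------------------------------
# Orientation

def orient_outward(mesh: TriangleMesh) -> TriangleMesh:
    """Make face windings consistent per component; flip closed components outward.

    Consistency is propagated breadth-first over the face-adjacency graph; a
    component whose constraints conflict raises :class:`NonOrientableError`.
    Closed components are globally flipped if their signed volume is negative;
    open components keep a consistent winding and log a warning (outwardness is
    undefined without an enclosed volume).
    """
    edges, counts, edge_faces, edge_dirs = mesh._edges()
    nf = mesh.n_faces
    # face adjacency across interior edges, with the directed traversals
    interior = counts == 2
    fa = edge_faces[interior]
    fd = edge_dirs[interior]
    adj: list[list[tuple[int, bool]]] = [[] for _ in range(nf)]
    for (f1, f2), (d1, d2) in zip(fa, fd):
        # consistent orientation <=> the shared edge is traversed oppositely
        same_dir = d1[0] == d2[0]
        adj[f1].append((int(f2), bool(same_dir)))
        adj[f2].append((int(f1), bool(same_dir)))
    flip = np.zeros(nf, dtype=bool)
    seen = np.full(nf, -1, dtype=np.int64)  # component id per face
    comp = 0
    for root in range(nf):
        if seen[root] >= 0:
            continue
        seen[root] = comp
        q = deque([root])
        while q:
            f = q.popleft()
            for g, same_dir in adj[f]:
                want = flip[f] ^ same_dir  # neighbour must flip iff traversals matched
                if seen[g] < 0:
                    seen[g] = comp
                    flip[g] = want
                    q.append(g)
                elif flip[g] != want:
                    raise NonOrientableError(
                        f"component {comp} of mesh {mesh.name!r} is non-orientable"
                    )
        comp += 1
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    out = TriangleMesh(mesh.vertices.copy(), faces, name=mesh.name)
    # globally flip closed components with inward winding
    edges2, counts2, edge_faces2, _ = out._edges()
    open_faces = np.zeros(nf, dtype=bool)
    for e in np.flatnonzero(counts2 == 1):
        open_faces[edge_faces2[e, 0]] = True
    tri = out.vertices[out.faces]
    vol_contrib = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    flipped_any = False
    for c in range(comp):
        mask = seen == c
        if open_faces[mask].any():
            log.warning(
                "orient_outward(%s): component %d is open; outward orientation undefined",
                mesh.name or "<unnamed>", c,
            )
            continue
        if vol_contrib[mask].sum() < 0:
            out.faces[mask] = out.faces[mask][:, ::-1]
            flipped_any = True
    if flipped_any:
        out.invalidate_cache()
    return out


def vertex_area(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex areas: A_i = (1/3) x sum of incident face areas.

    Their total equals the total surface area exactly (up to float summation).
    """
    _, areas = mesh.face_normals_areas()
    A = np.zeros(mesh.n_vertices)
    np.add.at(A, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    return A
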