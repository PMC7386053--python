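"""Triangulated surface meshes, neighbor rings, and the cylindrical grid projection.

Every phase-singularity detector in this package walks a closed loop of
neighbors around a candidate node and inspects the phase along that loop.
This module provides the spatial substrate for those walks:

* :class:`TriMesh` -- an oriented triangulated surface with vertices in mm.
* :func:`build_neighbor_index` -- edge-sharing adjacency, with manifoldness
  diagnostics.
* :func:`neighbor_ring_sorted` -- the closed ring of nodes at an exact graph
  distance (edge hops) from a center, sorted clockwise as seen from outside
  the surface.
* :class:`GridProjection` -- the bijection between mesh nodes and the cells
  of a rows x cols cylindrical unrolling (columns wrap around the seam).
* grid "diamond" rings -- the Manhattan-distance-N loop used by the 2D
  image-based detector.

Search radii are counted in *nodal* distances (edge hops on the mesh,
Manhattan steps on the grid), never in mm; physical distance enters only
through :func:`node_distance` (straight-line Euclidean, used by the 5 mm
cluster-refinement and matching rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MeshError(ValueError):
    """Raised for malformed meshes (bad indices, degenerate or non-manifold faces)."""


class OpenRingError(ValueError):
    """Raised when a node has no closed neighbor ring at the requested radius.

    Typically the node sits on (or within ``radius`` hops of) an open
    boundary.  Callers that scan all nodes skip such nodes and count them
    in their diagnostics.
    """


@dataclass
class NeighborRing:
    """A closed, simple loop of nodes at exact graph distance ``radius_N``.

    ``members`` are ordered clockwise with respect to the outward surface
    normal at ``center``, starting at the member with the lowest node index.
    """

    center: int
    radius_N: int
    members: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.members)


class TriMesh:
    """An oriented triangulated surface with vertex coordinates in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
        Node coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triples with consistent winding (outward normals).

    Raises
    ------
    MeshError
        If a face index is out of range, a face is degenerate (zero area),
        or two faces traverse a shared edge in the same direction (the mesh
        is not consistently oriented).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshError("face index out of range")
        self._check_degenerate()
        self._check_orientation()
        self._adjacency: list[np.ndarray] | None = None
        self._vertex_normals: np.ndarray | None = None
        self._ring_tables: dict[int, "RingTable"] = {}

    # -- invariants ---------------------------------------------------------

    def _check_degenerate(self) -> None:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area2 = np.linalg.norm(cross, axis=1)
        scale = max(np.ptp(v), 1.0)
        if np.any(area2 < 1e-12 * scale * scale):
            raise MeshError("degenerate (zero-area) face")

    def _check_orientation(self) -> None:
        # A consistently oriented manifold traverses every shared edge in
        # opposite directions from its two incident faces, i.e. no directed
        # edge repeats.
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = directed[:, 0] * len(self.vertices) + directed[:, 1]
        if len(np.unique(key)) != len(key):
            raise MeshError("inconsistent face winding: a directed edge appears twice")

    # -- derived structure --------------------------------------------------

    @property
    def node_count(self) -> int:
        return len(self.vertices)

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Per-node sorted arrays of direct (edge-sharing) neighbors."""
        if self._adjacency is None:
            index = build_neighbor_index(self)
            self._adjacency = [
                np.array(sorted(index[i]), dtype=np.int64) for i in range(self.node_count)
            ]
        return self._adjacency

    @property
    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted average of incident face normals (unit vectors)."""
        if self._vertex_normals is None:
            v = self.vertices
            f = self.faces
            fn = self.face_normals
            acc = np.zeros_like(v)
            for corner in range(3):
                i = f[:, corner]
                a = v[f[:, (corner + 1) % 3]] - v[i]
                b = v[f[:, (corner + 2) % 3]] - v[i]
                cosang = np.einsum("ij,ij->i", a, b) / (
                    np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
                )
                ang = np.arccos(np.clip(cosang, -1.0, 1.0))
                np.add.at(acc, i, fn * ang[:, None])
            norm = np.linalg.norm(acc, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._vertex_normals = acc / norm
        return self._vertex_normals


def build_neighbor_index(mesh: TriMesh) -> dict[int, set[int]]:
    """Adjacency map node -> set of direct neighbors (vertices sharing an edge).

    Raises
    ------
    MeshError
        If any undirected edge is shared by more than two faces
        (non-manifold), with the offending edge in the message.
    """
    f = mesh.faces
    n = mesh.node_count
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    key = lo * n + hi
    uniq, counts = np.unique(key, return_counts=True)
    if np.any(counts > 2):
        bad = uniq[np.argmax(counts > 2)]
        raise MeshError(
            f"non-manifold edge ({bad // n}, {bad % n}) shared by {counts.max()} faces"
        )
    index: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in zip(lo, hi):
        index[int(a)].add(int(b))
        index[int(b)].add(int(a))
    return index


def node_distance(mesh: TriMesh, i: int, j: int) -> float:
    """Straight-line Euclidean distance between two nodes, in mm."""
    return float(np.linalg.norm(mesh.vertices[i] - mesh.vertices[j]))


def _bfs_shell(adjacency: list[np.ndarray], center: int, radius: int) -> np.ndarray:
    """Nodes at graph distance exactly ``radius`` from ``center`` (sorted)."""
    dist = {center: 0}
    frontier = [center]
    for d in range(1, radius + 1):
        nxt = []
        for u in frontier:
            for v in adjacency[u]:
                v = int(v)
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return np.array(sorted(frontier), dtype=np.int64)


def _sort_ring_clockwise(mesh: TriMesh, center: int, shell: np.ndarray) -> np.ndarray:
    """Order shell members clockwise (viewed from outside) around ``center``.

    Members are sorted by the angle of their projection onto the tangent
    plane at the center (plane orthogonal to the angle-weighted vertex
    normal).  Ascending angle in the basis (e1, n x e1) is clockwise when
    viewed from outside, i.e. looking along -n.  The starting member is the
    lowest node index (its projection defines e1, so its angle is 0); equal
    angles tie-break by node index.
    """
    n = mesh.vertex_normals[center]
    rel = mesh.vertices[shell] - mesh.vertices[center]
    tang = rel - np.outer(rel @ n, n)
    # e1 from the lowest-index member with a non-degenerate projection
    e1 = None
    for k in np.argsort(shell):
        cand = tang[k]
        if np.linalg.norm(cand) > 1e-9:
            e1 = cand / np.linalg.norm(cand)
            break
    if e1 is None:
        raise OpenRingError(f"ring around node {center} degenerates onto its normal")
    e2 = np.cross(n, e1)
    ang = np.arctan2(tang @ e2, tang @ e1)
    ang = np.mod(ang, 2.0 * np.pi)
    order = np.lexsort((shell, ang))
    return shell[order]


def neighbor_ring_sorted(mesh: TriMesh, center: int, radius_N: int) -> NeighborRing:
    """The closed ring of nodes at graph distance exactly ``radius_N``.

    The ring is returned clockwise with respect to the outward surface
    normal at ``center``, starting at the lowest member index.  A ring is
    accepted as closed when every pair of cyclically consecutive members
    shares a mesh edge; otherwise :class:`OpenRingError` is raised (open
    boundary within ``radius_N`` hops).
    """
    if radius_N < 1:
        raise ValueError("radius_N must be >= 1")
    shell = _bfs_shell(mesh.adjacency, center, radius_N)
    if len(shell) < 3:
        raise OpenRingError(f"node {center} has no ring at radius {radius_N}")
    members = _sort_ring_clockwise(mesh, center, shell)
    adj = mesh.adjacency
    for a, b in zip(members, np.roll(members, -1)):
        if int(b) not in adj[int(a)]:  # np.ndarray __contains__ on ints is fine
            raise OpenRingError(
                f"ring around node {center} at radius {radius_N} is not closed"
            )
    return NeighborRing(center=center, radius_N=radius_N, members=members)


@dataclass
class RingTable:
    """All closed rings of one radius, grouped by ring length for vectorized use.

    ``groups`` maps ring length L to ``(centers, members)`` where ``centers``
    is an (m,) node array and ``members`` an (m, L) array of ring node
    indices in clockwise order.  ``skipped`` lists nodes without a closed
    ring at this radius (open boundary).
    """

    radius_N: int
    groups: dict[int, tuple[np.ndarray, np.ndarray]]
    skipped: np.ndarray


def ring_table(mesh: TriMesh, radius_N: int) -> RingTable:
    """Precompute (and cache on the mesh) every closed ring at one radius."""
    cached = mesh._ring_tables.get(radius_N)
    if cached is not None:
        return cached
    by_len: dict[int, list[tuple[int, np.ndarray]]] = {}
    skipped = []
    for node in range(mesh.node_count):
        try:
            ring = neighbor_ring_sorted(mesh, node, radius_N)
        except OpenRingError:
            skipped.append(node)
            continue
        by_len.setdefault(len(ring.members), []).append((node, ring.members))
    groups = {
        L: (
            np.array([c for c, _ in items], dtype=np.int64),
            np.stack([m for _, m in items]),
        )
        for L, items in by_len.items()
    }
    table = RingTable(radius_N=radius_N, groups=groups, skipped=np.array(skipped, dtype=np.int64))
    mesh._ring_tables[radius_N] = table
    return table


# ---------------------------------------------------------------------------
# Cylindrical grid projection
# ---------------------------------------------------------------------------


@dataclass
class GridProjection:
    """Bijection between grid cells (row, col) and node indices.

    The column axis wraps (cylinder seam); rows are clamped at top/bottom.
    The default layout is row-major: node = row * cols + col.
    """

    rows: int = 32
    cols: int = 64
    node_grid: np.ndarray = field(default=None)  # (rows, cols) int

    def __post_init__(self):
        if self.node_grid is None:
            self.node_grid = np.arange(self.rows * self.cols, dtype=np.int64).reshape(
                self.rows, self.cols
            )
        self.node_grid = np.asarray(self.node_grid, dtype=np.int64)
        if self.node_grid.shape != (self.rows, self.cols):
            raise ValueError("node_grid shape must be (rows, cols)")
        flat = self.node_grid.ravel()
        if len(np.unique(flat)) != len(flat):
            raise ValueError("node_grid is not a bijection")
        self._cells = np.empty((flat.max() + 1, 2), dtype=np.int64)
        self._cells.fill(-1)
        rr, cc = np.divmod(np.arange(self.rows * self.cols), self.cols)
        self._cells[flat] = np.column_stack([rr, cc])

    def node_of(self, row: int, col: int) -> int:
        if not 0 <= row < self.rows:
            raise IndexError(f"row {row} outside 0..{self.rows - 1}")
        return int(self.node_grid[row, col % self.cols])

    def cell_of(self, node: int) -> tuple[int, int]:
        r, c = self._cells[node]
        return int(r), int(c)

    @property
    def cell_array(self) -> np.ndarray:
        """(max_node+1, 2) array of (row, col) per node; -1 for unmapped nodes."""
        return self._cells

    def frame_to_grid(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-node values onto the (rows, cols) grid."""
        return np.asarray(values)[self.node_grid]

    def to_csv(self, path) -> None:
        rr, cc = np.divmod(np.arange(self.rows * self.cols), self.cols)
        pd.DataFrame(
            {"node": self.node_grid.ravel(), "row": rr, "col": cc}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GridProjection":
        df = pd.read_csv(path)
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        grid = np.empty((rows, cols), dtype=np.int64)
        grid[df["row"].to_numpy(), df["col"].to_numpy()] = df["node"].to_numpy()
        return cls(rows=rows, cols=cols, node_grid=grid)


def grid_diamond_ring(
    projection: GridProjection, row: int, col: int, radius_N: int
) -> np.ndarray | None:
    """Manhattan-distance-N "diamond" ring, clockwise, as (4N, 2) cells.

    Starts at the top cell (row - N, col) and proceeds clockwise
    (up -> right -> down -> left).  Columns wrap across the seam; if any
    cell falls outside the row range the ring does not exist and ``None``
    is returned (the caller skips the node).
    """
    if radius_N < 1:
        raise ValueError("radius_N must be >= 1")
    if row - radius_N < 0 or row + radius_N >= projection.rows:
        return None
    pts = []
    for i in range(radius_N):  # top -> right
        pts.append((row - radius_N + i, col + i))
    for i in range(radius_N):  # right -> bottom
        pts.append((row + i, col + radius_N - i))
    for i in range(radius_N):  # bottom -> left
        pts.append((row + radius_N - i, col - i))
    for i in range(radius_N):  # left -> top
        pts.append((row - i, col - radius_N + i))
    out = np.array(pts, dtype=np.int64)
    out[:, 1] %= projection.cols
    return out


def grid_ring_table(projection: GridProjection, radius_N: int) -> RingTable:
    """Diamond rings for every grid node with full row clearance, vectorized."""
    rows, cols = projection.rows, projection.cols
    r0 = np.arange(radius_N, rows - radius_N)
    c0 = np.arange(cols)
    if len(r0) == 0:
        return RingTable(radius_N, {}, projection.node_grid.ravel().copy())
    template = grid_diamond_ring(projection, radius_N, 0, radius_N)
    dr = template[:, 0] - radius_N
    dc = template[:, 1].copy()
    dc[dc > cols // 2] -= cols  # undo the wrap applied by grid_diamond_ring
    rr, cc = np.meshgrid(r0, c0, indexing="ij")
    ring_r = rr.ravel()[:, None] + dr[None, :]
    ring_c = (cc.ravel()[:, None] + dc[None, :]) % cols
    centers = projection.node_grid[rr.ravel(), cc.ravel()]
    members = projection.node_grid[ring_r, ring_c]
    skipped_rows = np.concatenate(
        [np.arange(0, radius_N), np.arange(rows - radius_N, rows)]
    )
    skipped = projection.node_grid[skipped_rows, :].ravel()
    return RingTable(
        radius_N=radius_N,
        groups={4 * radius_N: (centers.astype(np.int64), members.astype(np.int64))},
        skipped=np.sort(skipped),
    )


# ---------------------------------------------------------------------------
# Mesh I/O (ASCII PLY / OBJ via trimesh)
# ---------------------------------------------------------------------------


def save_mesh(mesh: TriMesh, path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path = str(path)
    if path.endswith(".ply"):
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    elif path.endswith(".obj"):
        with open(path, "w") as fh:
            fh.write(trimesh.exchange.obj.export_obj(tm))
    else:
        raise ValueError("mesh path must end in .ply or .obj")


def load_mesh(path) -> TriMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))
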