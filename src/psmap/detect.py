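"""The four single-frame phase-singularity detectors and cluster refinement.

A phase singularity (PS) is a point around which the instantaneous phase
progresses monotonically through a full 2*pi cycle; it marks the tip of a
re-entrant spiral wave (rotor).  Four detection strategies are implemented,
all operating on a single phase frame:

1. ``detect_alg1`` -- image-processing pipeline on the 2D cylindrical
   projection: Canny edges of the phase-gradient magnitude, edge-line
   endpoints as candidates, monotonic-loop confirmation on a clockwise
   "diamond" ring, centroid clustering.  Default threshold 1.5*pi, N=3.
2. ``detect_alg2`` -- monotonic-loop test on the clockwise triangulation
   ring of every mesh node, followed by DBSCAN-style refinement.  Default
   threshold 1.5*pi, N=3.
3. ``detect_alg3`` -- topological charge by kernel convolution on the 2D
   projection (see :mod:`psmap.kernels`); cells where |2*pi*n_t| clears the
   threshold are PSs, with chirality = sign(n_t).  Default 1.9*pi, sobel3.
4. ``detect_alg4`` -- topological charge on the 3D mesh: signed count of
   large "phase jumps" along the clockwise neighbor ring; an odd count is a
   PS.  Default jump threshold 3.5 rad (~1.1*pi), N=1.

Chirality is +1 when the phase increases along the clockwise loop
(equivalently, positive winding of the plaquette path traversed clockwise
on screen), for all four algorithms.

``dbscan_refine`` merges clusters of detections that are mesh-adjacent or
within 5 mm of each other, keeping the member with the greatest loop
gradient -- the modified density-based clustering used to de-duplicate PS
detections on a triangulated surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kernels import ANCHOR, CHARGE_NORM, FLIP, KERNELS
from .mesh import GridProjection, RingTable, TriMesh, grid_diamond_ring, ring_table

TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angles to the half-open interval (-pi, pi].

    Returns x + 2*pi*k for the unique integer k landing in range; both +pi
    and -pi map to +pi.
    """
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), TWO_PI)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

KERNEL_NAMES = ("sobel3", "sobel5", "nabla2", "nabla3")


@dataclass
class DetectorParams:
    """Configuration of one detector.

    ``phase_gradient_threshold`` is in radians: the minimum max-min phase
    spread along the detection loop (algorithms 1, 2), the minimum
    |2*pi*n_t| (algorithm 3), or the minimum single-step jump (algorithm 4).
    ``radius_N`` counts nodal distances (algorithms 1, 2, 4);
    ``kernel_name`` selects the convolution stencil (algorithm 3).
    """

    algorithm: int
    phase_gradient_threshold: float
    radius_N: int | None = None
    kernel_name: str | None = None
    refine: str = "none"  # none | centroid | dbscan
    dbscan_distance: float = 5.0
    canny_low: float = 0.3 * np.pi
    canny_high: float = 0.6 * np.pi

    def __post_init__(self):
        if self.algorithm not in (1, 2, 3, 4):
            raise ValueError("algorithm must be 1, 2, 3 or 4")
        if not 0.0 < self.phase_gradient_threshold <= TWO_PI:
            raise ValueError("phase_gradient_threshold must lie in (0, 2*pi]")
        if self.refine not in ("none", "centroid", "dbscan"):
            raise ValueError("refine must be none, centroid or dbscan")
        if self.algorithm == 3:
            if self.kernel_name not in KERNEL_NAMES:
                raise ValueError(f"kernel_name must be one of {KERNEL_NAMES}")
        else:
            if self.radius_N is None or not 1 <= self.radius_N <= 8:
                raise ValueError("radius_N must lie in 1..8")
            if self.algorithm == 1 and self.radius_N < 2:
                raise ValueError("algorithm 1 requires radius_N >= 2")


def default_params(algorithm: int, refine: str | None = None) -> DetectorParams:
    """The default parameter set of each algorithm.

    Algorithm 1: 1.5*pi, N=3, centroid clustering.  Algorithm 2: 1.5*pi,
    N=3, DBSCAN.  Algorithm 3: 1.9*pi, sobel3, no refinement.  Algorithm 4:
    3.5 rad (~1.1*pi), N=1, no refinement.  ``refine`` overrides the
    default refinement (e.g. "dbscan" for algorithms 3/4 + DBSCAN).
    """
    if algorithm not in (1, 2, 3, 4):
        raise ValueError("algorithm must be 1, 2, 3 or 4")
    table = {
        1: DetectorParams(1, 1.5 * np.pi, radius_N=3, refine="centroid"),
        2: DetectorParams(2, 1.5 * np.pi, radius_N=3, refine="dbscan"),
        3: DetectorParams(3, 1.9 * np.pi, kernel_name="sobel3", refine="none"),
        4: DetectorParams(4, 3.5, radius_N=1, refine="none"),
    }
    params = table[algorithm]
    if refine is not None:
        params = replace(params, refine=refine)
    return params


# ---------------------------------------------------------------------------
# Loop statistics
# ---------------------------------------------------------------------------


@dataclass
class LoopStats:
    gradient: float
    monotonic: bool
    direction: int


def _loop_stats_batch(R: np.ndarray):
    """Vectorized monotonic-loop statistics for rings stacked in rows.

    A closed loop is monotonic when, traversed from its minimum-phase
    member, the raw phases are non-decreasing with the single wrap crossing
    at the closing step (or the mirror-image decreasing case).  Returns
    (gradient, monotonic, direction) arrays; gradient is max-min of the raw
    phases, direction +1 for increasing / -1 for decreasing loops.
    """
    R = np.asarray(R, dtype=float)
    m, L = R.shape
    rows = np.arange(m)[:, None]
    idx = np.arange(L)
    g = R.max(axis=1) - R.min(axis=1)
    rot_min = R[rows, (np.argmin(R, axis=1)[:, None] + idx) % L]
    inc = np.all(np.diff(rot_min, axis=1) >= 0, axis=1)
    rot_max = R[rows, (np.argmax(R, axis=1)[:, None] + idx) % L]
    dec = np.all(np.diff(rot_max, axis=1) <= 0, axis=1)
    nonconstant = g > 0
    inc &= nonconstant
    dec &= nonconstant
    return g, inc | dec, inc.astype(np.int8) - dec.astype(np.int8)


def loop_monotonic_stats(loop_phases) -> LoopStats:
    """Monotonic-loop statistics for a single ordered closed loop of phases."""
    ph = np.asarray(loop_phases, dtype=float)
    if ph.ndim != 1 or len(ph) < 3:
        raise ValueError("a loop needs at least 3 members")
    g, mono, dirn = _loop_stats_batch(ph[None, :])
    return LoopStats(gradient=float(g[0]), monotonic=bool(mono[0]), direction=int(dirn[0]))


# ---------------------------------------------------------------------------
# Topological charge on the 2D grid
# ---------------------------------------------------------------------------


@dataclass
class ChargeField:
    """Per-cell topological charge n_t with the wrapped gradient fields.

    ``charge[r, c]`` estimates the winding number of the clockwise loop
    around the plaquette anchored at (r, c); |2*pi*charge| is the quantity
    thresholded by algorithm 3.
    """

    charge: np.ndarray
    kx: np.ndarray
    ky: np.ndarray
    kernel_name: str


def _apply_stencil(field: np.ndarray, K: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """Correlate ``field`` with stencil ``K`` anchored at ``anchor``.

    Columns are periodic (cylinder seam); row shifts beyond the boundary
    contribute zero (the caller blanks the affected boundary rows).
    """
    out = np.zeros_like(field)
    kr, kc = K.shape
    for a in range(kr):
        for b in range(kc):
            w = K[a, b]
            if w == 0.0:
                continue
            shifted = np.roll(field, -(b - anchor[1]), axis=1)
            dr = a - anchor[0]
            tmp = np.zeros_like(shifted)
            if dr == 0:
                tmp = shifted
            elif dr > 0:
                tmp[:-dr] = shifted[dr:]
            else:
                tmp[-dr:] = shifted[:dr]
            out = out + w * tmp
    return out


def topological_charge_2d(frame: np.ndarray, kernel_name: str = "sobel3") -> ChargeField:
    """Topological charge per grid cell by stencil convolution.

    ``kx``/``ky`` are the wrapped one-step phase differences along columns
    (periodic across the seam) and rows; the charge is the convolution form
    of the loop line-integral of the phase gradient, normalized by the
    kernel's loop multiplicity so an ideal singularity carries charge +-1.
    """
    if kernel_name not in KERNELS:
        raise ValueError(f"unknown kernel {kernel_name!r}")
    frame = np.asarray(frame, dtype=float)
    Dx, Dy = KERNELS[kernel_name]
    if frame.shape[0] < Dx.shape[0] + 1 or frame.shape[1] < Dx.shape[1]:
        raise ValueError("frame smaller than kernel")
    kx = wrap_phase(np.roll(frame, -1, axis=1) - frame)  # step to next column
    ky = np.zeros_like(frame)
    ky[:-1] = wrap_phase(frame[1:] - frame[:-1])  # step to next row
    ax, ay = ANCHOR[kernel_name]
    # line integral l = Dx * ky + Dy * kx, with each stencil oriented so the
    # charge sign equals the winding number (see kernels.FLIP)
    if FLIP[kernel_name]:
        Dx, Dy = Dx[::-1, ::-1], Dy[::-1, ::-1]
    raw = _apply_stencil(ky, Dx, ax) + _apply_stencil(kx, Dy, ay)
    charge = raw / (TWO_PI * CHARGE_NORM[kernel_name])
    # Blank rows whose stencil support crosses the open top/bottom boundary
    # (ky's synthetic last row included).
    reach_up = max(ax[0], ay[0])
    reach_dn = max(Dx.shape[0] - 1 - ax[0], Dy.shape[0] - 1 - ay[0]) + 1
    charge[:reach_up] = 0.0
    charge[frame.shape[0] - reach_dn :] = 0.0
    return ChargeField(charge=charge, kx=kx, ky=ky, kernel_name=kernel_name)


def plaquette_winding(frame: np.ndarray) -> np.ndarray:
    """Brute-force winding number of every 2x2 plaquette (clockwise path).

    Reference implementation of the topological charge: the sum of wrapped
    phase differences around the four corners of each plaquette, divided by
    2*pi.  The last row (no plaquette) is zero.
    """
    frame = np.asarray(frame, dtype=float)
    a = frame
    b = np.roll(frame, -1, axis=1)  # (r, c+1)
    d = np.vstack([frame[1:], frame[-1:]])  # (r+1, c)
    c = np.roll(d, -1, axis=1)  # (r+1, c+1)
    w = (
        wrap_phase(b - a)
        + wrap_phase(c - b)
        + wrap_phase(d - c)
        + wrap_phase(a - d)
    ) / TWO_PI
    w[-1] = 0.0
    return w


# ---------------------------------------------------------------------------
# Per-frame detectors (low-level; arrays in, arrays out)
# ---------------------------------------------------------------------------


def _empty():
    z = np.array([], dtype=np.int64)
    return z, z.astype(np.int8), np.array([], dtype=float)


def _detect_monotonic_rings(phases: np.ndarray, table: RingTable, threshold: float):
    nodes, chir, grad = [], [], []
    for _, (centers, members) in table.groups.items():
        R = phases[members]
        g, mono, dirn = _loop_stats_batch(R)
        keep = mono & (g >= threshold)
        nodes.append(centers[keep])
        chir.append(dirn[keep])
        grad.append(g[keep])
    if not nodes:
        return _empty()
    return (
        np.concatenate(nodes),
        np.concatenate(chir).astype(np.int8),
        np.concatenate(grad),
    )


def detect_alg2_frame(
    phases: np.ndarray, mesh: TriMesh, params: DetectorParams, table: RingTable | None = None
):
    """Monotonic-loop detector on mesh rings for one frame (unrefined)."""
    if table is None:
        table = ring_table(mesh, params.radius_N)
    return _detect_monotonic_rings(phases, table, params.phase_gradient_threshold)


def detect_alg4_frame(
    phases: np.ndarray, mesh: TriMesh, params: DetectorParams, table: RingTable | None = None
):
    """Odd-phase-jump (3D topological charge) detector for one frame (unrefined).

    Along each clockwise ring the signed jump count is
    s = #(raw consecutive differences < -threshold) - #(differences > +threshold),
    including the closing pair; |s| odd marks a PS with chirality sign(s).
    """
    if table is None:
        table = ring_table(mesh, params.radius_N)
    thr = params.phase_gradient_threshold
    nodes, chir, grad = [], [], []
    for _, (centers, members) in table.groups.items():
        R = phases[members]
        D = np.roll(R, -1, axis=1) - R  # raw (unwrapped) differences, closing pair included
        s = (D < -thr).sum(axis=1) - (D > thr).sum(axis=1)
        keep = (np.abs(s) % 2) == 1
        nodes.append(centers[keep])
        chir.append(np.sign(s[keep]))
        grad.append(R[keep].max(axis=1) - R[keep].min(axis=1) if keep.any() else np.array([]))
    if not nodes:
        return _empty()
    return (
        np.concatenate(nodes),
        np.concatenate(chir).astype(np.int8),
        np.concatenate(grad).astype(float),
    )


def detect_alg3_frame(frame2d: np.ndarray, params: DetectorParams, projection: GridProjection):
    """Kernel topological-charge detector for one 2D frame (unrefined)."""
    cf = topological_charge_2d(frame2d, params.kernel_name)
    val = TWO_PI * cf.charge
    rr, cc = np.nonzero(np.abs(val) >= params.phase_gradient_threshold)
    nodes = projection.node_grid[rr, cc]
    return nodes, np.sign(val[rr, cc]).astype(np.int8), np.abs(val[rr, cc])


def _gradient_magnitude(frame2d: np.ndarray) -> np.ndarray:
    kx = wrap_phase(np.roll(frame2d, -1, axis=1) - frame2d)
    ky = np.zeros_like(frame2d)
    ky[:-1] = wrap_phase(frame2d[1:] - frame2d[:-1])
    ky[-1] = ky[-2]
    return np.hypot(kx, ky)


def _edge_endpoints(edges: np.ndarray) -> np.ndarray:
    """Edge pixels with exactly one 8-connected edge neighbor (seam-aware)."""
    e = edges.astype(np.int8)
    cnt = np.zeros_like(e, dtype=np.int16)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(e, -dc, axis=1)
            tmp = np.zeros_like(shifted)
            if dr == 0:
                tmp = shifted
            elif dr > 0:
                tmp[:-dr] = shifted[dr:]
            else:
                tmp[-dr:] = shifted[:dr]
            cnt += tmp
    return edges & (cnt == 1)


def _cluster_pixels(points: np.ndarray, cols: int) -> list[np.ndarray]:
    """8-connected components of (row, col) pixels with column wrap."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dr = abs(int(points[i, 0]) - int(points[j, 0]))
            dcol = abs(int(points[i, 1]) - int(points[j, 1]))
            dc = min(dcol, cols - dcol)
            if dr <= 1 and dc <= 1:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [np.array(v, dtype=np.int64) for v in comps.values()]


def detect_alg1_frame(frame2d: np.ndarray, projection: GridProjection, params: DetectorParams):
    """Image-processing detector for one 2D frame.

    Canny edges of the wrapped-gradient magnitude (seam-periodic), edge-line
    endpoints as PS candidates, clockwise diamond-ring monotonic-loop
    confirmation, then 8-connected centroid clustering (when
    ``params.refine == "centroid"``).
    """
    from skimage.feature import canny

    rows, cols = frame2d.shape
    gm = _gradient_magnitude(frame2d)
    pad = min(8, cols // 2)
    padded = np.concatenate([gm[:, -pad:], gm, gm[:, :pad]], axis=1)
    edges = canny(
        padded, sigma=1.0, low_threshold=params.canny_low, high_threshold=params.canny_high
    )[:, pad:-pad]
    if not edges.any():
        return _empty()
    cand = _edge_endpoints(edges)
    # A closed edge contour has no free ends: it encircles a candidate
    # singularity, so every pixel of an endpoint-free component is a
    # candidate and the monotonic-loop test arbitrates.
    pix = np.argwhere(edges)
    for comp in _cluster_pixels(pix, cols):
        if not cand[pix[comp, 0], pix[comp, 1]].any():
            cand[pix[comp, 0], pix[comp, 1]] = True
    rr, cc = np.nonzero(cand)
    kept_r, kept_c, kept_chir, kept_grad = [], [], [], []
    for r, c in zip(rr, cc):
        ring = grid_diamond_ring(projection, int(r), int(c), params.radius_N)
        if ring is None:
            continue
        stats = loop_monotonic_stats(frame2d[ring[:, 0], ring[:, 1]])
        if stats.monotonic and stats.gradient >= params.phase_gradient_threshold:
            kept_r.append(int(r))
            kept_c.append(int(c))
            kept_chir.append(stats.direction)
            kept_grad.append(stats.gradient)
    if not kept_r:
        return _empty()
    pts = np.column_stack([kept_r, kept_c])
    chir = np.array(kept_chir, dtype=np.int8)
    grad = np.array(kept_grad, dtype=float)
    if params.refine != "centroid":
        nodes = projection.node_grid[pts[:, 0], pts[:, 1]]
        return nodes, chir, grad
    nodes, out_chir, out_grad = [], [], []
    for comp in _cluster_pixels(pts, cols):
        r_mean = pts[comp, 0].mean()
        ang = 2.0 * np.pi * pts[comp, 1] / cols
        mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        c_mean = (mean_ang / (2.0 * np.pi) * cols) % cols
        r_snap = int(np.ceil(r_mean - 0.5))  # ties -> lower row
        c_snap = int(np.ceil(c_mean - 0.5)) % cols
        r_snap = min(max(r_snap, 0), rows - 1)
        best = comp[np.argmax(grad[comp])]
        nodes.append(projection.node_grid[r_snap, c_snap])
        out_chir.append(chir[best])
        out_grad.append(grad[best])
    return (
        np.array(nodes, dtype=np.int64),
        np.array(out_chir, dtype=np.int8),
        np.array(out_grad, dtype=float),
    )


# ---------------------------------------------------------------------------
# DBSCAN-style cluster refinement
# ---------------------------------------------------------------------------


def dbscan_refine(
    nodes: np.ndarray,
    chirality: np.ndarray,
    gradient: np.ndarray,
    mesh: TriMesh,
    distance: float = 5.0,
):
    """Merge same-frame detections that are mesh-adjacent or within ``distance`` mm.

    Clusters are the connected components of the graph whose edges join
    detections that share a mesh edge or lie within ``distance`` of each
    other; each cluster is replaced by its member with the greatest loop
    gradient (ties broken toward the lowest node index).  Idempotent and
    never increases the count.
    """
    n = len(nodes)
    if n <= 1:
        return nodes, chirality, gradient
    from scipy.spatial import cKDTree

    coords = mesh.vertices[nodes]
    pairs = cKDTree(coords).query_pairs(r=distance, output_type="ndarray")
    pos = {int(node): i for i, node in enumerate(nodes)}
    adj_pairs = []
    for i, node in enumerate(nodes):
        for nb in mesh.adjacency[int(node)]:
            j = pos.get(int(nb))
            if j is not None and j > i:
                adj_pairs.append((i, j))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in list(map(tuple, pairs)) + adj_pairs:
        parent[find(int(i))] = find(int(j))
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    keep = []
    for members in comps.values():
        members = np.array(members)
        # max gradient, ties -> lowest node index
        order = np.lexsort((nodes[members], -gradient[members]))
        keep.append(members[order[0]])
    keep = np.sort(np.array(keep))
    return nodes[keep], chirality[keep], gradient[keep]


# ---------------------------------------------------------------------------
# Public multi-frame API
# ---------------------------------------------------------------------------


def detect_frame(
    frame_values: np.ndarray,
    params: DetectorParams,
    mesh: TriMesh | None = None,
    projection: GridProjection | None = None,
    table: RingTable | None = None,
):
    """Run one detector on a single frame of per-node phases.

    Returns ``(nodes, chirality, loop_gradient)`` arrays, refined according
    to ``params.refine``.
    """
    alg = params.algorithm
    if alg in (1, 3):
        if projection is None:
            raise ValueError(f"algorithm {alg} requires a grid projection")
        frame2d = projection.frame_to_grid(frame_values)
        if alg == 1:
            nodes, chir, grad = detect_alg1_frame(frame2d, projection, params)
        else:
            nodes, chir, grad = detect_alg3_frame(frame2d, params, projection)
    else:
        if mesh is None:
            raise ValueError(f"algorithm {alg} requires a mesh")
        if table is None:
            table = ring_table(mesh, params.radius_N)
        if alg == 2:
            nodes, chir, grad = detect_alg2_frame(frame_values, mesh, params, table)
        else:
            nodes, chir, grad = detect_alg4_frame(frame_values, mesh, params, table)
    if params.refine == "dbscan" and len(nodes) > 1:
        if mesh is None:
            raise ValueError("dbscan refinement requires a mesh")
        nodes, chir, grad = dbscan_refine(nodes, chir, grad, mesh, params.dbscan_distance)
    return nodes, chir, grad


def detect(
    phase,
    params: DetectorParams,
    mesh: TriMesh | None = None,
    projection: GridProjection | None = None,
) -> pd.DataFrame:
    """Run a detector frame-independently over a phase sequence.

    ``phase`` is a frames x nodes array (or an object with a ``.phase``
    attribute).  Returns a DataFrame with columns
    frame, node, row, col, chirality, loop_gradient (row/col are -1 when no
    projection is given or a node is unmapped).
    """
    values = getattr(phase, "phase", phase)
    if mesh is None:
        mesh = getattr(phase, "mesh", None)
    if projection is None:
        projection = getattr(phase, "projection", None)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("phase must be frames x nodes")
    table = None
    if params.algorithm in (2, 4) and mesh is not None:
        table = ring_table(mesh, params.radius_N)
    frames_out, nodes_out, chir_out, grad_out = [], [], [], []
    for t in range(values.shape[0]):
        nodes, chir, grad = detect_frame(
            values[t], params, mesh=mesh, projection=projection, table=table
        )
        frames_out.append(np.full(len(nodes), t, dtype=np.int64))
        nodes_out.append(nodes)
        chir_out.append(chir)
        grad_out.append(grad)
    frame = np.concatenate(frames_out) if frames_out else np.array([], dtype=np.int64)
    node = np.concatenate(nodes_out) if nodes_out else np.array([], dtype=np.int64)
    chir = np.concatenate(chir_out) if chir_out else np.array([], dtype=np.int8)
    grad = np.concatenate(grad_out) if grad_out else np.array([], dtype=float)
    if projection is not None and len(node):
        cells = projection.cell_array[node]
        row, col = cells[:, 0], cells[:, 1]
    else:
        row = np.full(len(node), -1, dtype=np.int64)
        col = np.full(len(node), -1, dtype=np.int64)
    return pd.DataFrame(
        {
            "frame": frame,
            "node": node,
            "row": row,
            "col": col,
            "chirality": chir.astype(np.int64) if len(chir) else chir,
            "loop_gradient": grad,
        }
    )
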