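"""Conforming crack meshes for a rectangular plate with one seam incision.

The mesher is the package's synthetic-input generator: it produces the only
geometry the downstream solver ever sees.  The construction is a single
layered "O-grid" wrapped around the incision:

* **layer 0** is the incision itself, traversed on both faces.  Interior
  vertices are duplicated into coincident *seam pairs* (upper/lower face);
  each tip is a single node.
* successive layers are closed offset curves ("stadium" curves around the
  tip-to-tip chord, plus the incision's deviation from the chord, which
  decays with offset distance).  Near the tips the layers are circular caps,
  so the elements between layer 0 and layer 1 at a tip degenerate from
  quadrilaterals into a fan of triangles -- the classic spider-web crack-tip
  pattern produced by a sweeping strategy.
* layer radii grow geometrically: the first ``n_rings`` layers form the
  contour-integral rings, later layers coarsen toward the far field, and the
  last few layers blend onto the exact square plate boundary.

Everything is deterministic; there is no randomness anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CrackPath, PlateSpec, chord_span

__all__ = [
    "MeshParams",
    "CrackMesh",
    "MeshError",
    "build_mesh",
    "snap_seam_nodes",
    "merge_seam",
]


class MeshError(RuntimeError):
    """Mesh generation failed (infeasible geometry or degenerate elements)."""


def _cross2(a, b):
    """z-component of the cross product of stacked 2-vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass(frozen=True)
class MeshParams:
    """Discretization knobs.

    ``n_rings`` contour rings of radius ``r_inner * ring_growth**(k-1)`` wrap
    each tip (ring radii must stay well inside the plate and away from the
    other tip).  ``n_spokes`` is the number of fan elements over each tip cap.
    ``far_field_size`` caps the radial layer thickness away from the crack.
    """

    n_rings: int = 10
    r_inner: float | None = None  # default: a / 50
    ring_growth: float = 1.35
    n_spokes: int = 32
    far_field_size: float = 2.0e-3
    outer_growth: float = 1.15
    n_blend: int = 16
    crack_spacing_cap_frac: float = 1.0 / 24.0  # max crack-vertex spacing / a

    def __post_init__(self) -> None:
        if self.n_rings < 10:
            raise MeshError(f"n_rings must be >= 10 (got {self.n_rings})")
        if not (1.0 < self.ring_growth <= 2.0):
            raise MeshError(f"ring_growth must lie in (1, 2], got {self.ring_growth}")
        if self.n_spokes < 8 or self.n_spokes % 2:
            raise MeshError(f"n_spokes must be even and >= 8, got {self.n_spokes}")
        if self.r_inner is not None and not self.r_inner > 0:
            raise MeshError("r_inner must be positive")
        if not self.far_field_size > 0:
            raise MeshError("far_field_size must be positive")
        if not self.outer_growth > 1.0:
            raise MeshError("outer_growth must exceed 1")
        if self.n_blend < 2:
            raise MeshError("n_blend must be >= 2")

    def resolved_r_inner(self, a: float) -> float:
        return self.r_inner if self.r_inner is not None else a / 50.0


@dataclass
class CrackMesh:
    """A conforming plate mesh with a seam incision and tip contour rings.

    Elements are 3-node triangles (``tris``) and 4-node quadrilaterals
    (``quads``), both counterclockwise.  A global element id enumerates the
    triangles first, then the quadrilaterals.
    """

    nodes: np.ndarray  # (N, 2) coordinates [m]
    tris: np.ndarray  # (nt, 3) int
    quads: np.ndarray  # (nq, 4) int
    seam_pairs: np.ndarray  # (P, 2) int: (upper, lower), ordered left -> right
    seam_normals: np.ndarray  # (P, 2) unit crack normals (upper side)
    seam_arclengths: np.ndarray  # (P,) arc length of each pair from the left tip
    midpoint_pair: tuple  # (upper, lower) node ids at the incision midpoint
    tip_nodes: dict  # {"left": id, "right": id}
    tip_extension: dict  # {"left": unit vec, "right": unit vec} outward tangents
    tip_rings: dict  # {"left": [array of element ids per ring], "right": [...]}
    boundary_edges: dict  # {"left"/"right"/"top"/"bottom": (n, 2) node-id pairs}
    plate: PlateSpec = None  # type: ignore[assignment]
    path: CrackPath = None  # type: ignore[assignment]
    params: MeshParams = None  # type: ignore[assignment]
    has_seam: bool = True

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tris) + len(self.quads)

    def element_nodes(self, eid: int) -> np.ndarray:
        nt = len(self.tris)
        return self.tris[eid] if eid < nt else self.quads[eid - nt]

    def iter_elements(self):
        """Yield (element_id, node_id_array) for all elements."""
        for i, tri in enumerate(self.tris):
            yield i, tri
        nt = len(self.tris)
        for j, quad in enumerate(self.quads):
            yield nt + j, quad

    def element_areas(self) -> np.ndarray:
        """Signed polygon areas of all elements (tris then quads)."""
        out = np.empty(self.n_elements)
        x = self.nodes
        if len(self.tris):
            p = x[self.tris]
            out[: len(self.tris)] = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        if len(self.quads):
            p = x[self.quads]
            a1 = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            a2 = 0.5 * _cross2(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
            out[len(self.tris):] = a1 + a2
        return out

    def copy(self) -> "CrackMesh":
        return CrackMesh(
            nodes=self.nodes.copy(),
            tris=self.tris.copy(),
            quads=self.quads.copy(),
            seam_pairs=self.seam_pairs.copy(),
            seam_normals=self.seam_normals.copy(),
            seam_arclengths=self.seam_arclengths.copy(),
            midpoint_pair=tuple(self.midpoint_pair),
            tip_nodes=dict(self.tip_nodes),
            tip_extension={k: v.copy() for k, v in self.tip_extension.items()},
            tip_rings={k: [r.copy() for r in v] for k, v in self.tip_rings.items()},
            boundary_edges={k: v.copy() for k, v in self.boundary_edges.items()},
            plate=self.plate,
            path=self.path,
            params=self.params,
            has_seam=self.has_seam,
        )


# ---------------------------------------------------------------------------
# layer-curve machinery
# ---------------------------------------------------------------------------

def _smoothstep(t: float) -> float:
    t = min(1.0, max(0.0, t))
    return t * t * (3.0 - 2.0 * t)


def _crack_arclengths(a: float, r_inner: float, growth: float, cap_frac: float,
                      min_half: int) -> np.ndarray:
    """Arc-length positions of crack vertices, graded geometrically from both
    tips, symmetric, with the midpoint as a vertex."""
    steps = []
    pos = 0.0
    j = 0
    cap = a * cap_frac
    while pos < a:
        d = min(r_inner * growth**j, cap)
        steps.append(d)
        pos += d
        j += 1
    while len(steps) < min_half:
        # refine the cap until enough vertices exist for the ring windows
        cap *= 0.5
        steps, pos, j = [], 0.0, 0
        while pos < a:
            d = min(r_inner * growth**j, cap)
            steps.append(d)
            pos += d
            j += 1
    half = np.cumsum(steps) * (a / pos)
    half[-1] = a  # exact midpoint
    s = np.concatenate([[0.0], half, 2.0 * a - half[:-1][::-1], [2.0 * a]])
    return np.unique(s)


class _Stadium:
    """Closed offset curve at distance t around the horizontal chord
    [(-c, y0), (c, y0)], parameterized by arc length from the top center,
    advancing in +x (clockwise around the enclosed region)."""

    def __init__(self, c: float, y0: float, t: float):
        self.c, self.y0, self.t = c, y0, t
        self.cap = math.pi * t
        self.L = 4.0 * c + 2.0 * self.cap

    def point(self, arc: float) -> tuple[float, float]:
        c, y0, t, cap = self.c, self.y0, self.t, self.cap
        arc = arc % self.L if self.L > 0 else 0.0
        if arc < c:  # top, center -> right
            return arc, y0 + t
        arc -= c
        if arc < cap:  # right cap, theta from +90 to -90 deg
            th = math.pi / 2 - math.pi * (arc / cap if cap else 0.0)
            return c + t * math.cos(th), y0 + t * math.sin(th)
        arc -= cap
        if arc < 2 * c:  # bottom, right -> left
            return c - arc, y0 - t
        arc -= 2 * c
        if arc < cap:  # left cap, theta from -90 down around to -270 (=+90)
            th = -math.pi / 2 - math.pi * (arc / cap if cap else 0.0)
            return -c + t * math.cos(th), y0 + t * math.sin(th)
        arc -= cap
        return -c + arc, y0 + t  # top, left -> center

    def on_flat(self, arc: float) -> tuple[bool, float, bool]:
        """(is_flat, chord x, is_upper) for the point at ``arc``."""
        c, cap = self.c, self.cap
        arc = arc % self.L if self.L > 0 else 0.0
        if arc < c:
            return True, arc, True
        if arc < c + cap:
            return False, 0.0, True
        if arc < 3 * c + cap:
            return True, c - (arc - c - cap), False
        if arc < 3 * c + 2 * cap:
            return False, 0.0, False
        return True, arc - (3 * c + 2 * cap) - c, True


def _square_radial(theta: float, hw: float, hh: float) -> tuple[float, float]:
    """Point on the rectangle boundary along direction theta from the origin."""
    ct, st = math.cos(theta), math.sin(theta)
    r = math.inf
    if abs(ct) > 1e-15:
        r = min(r, hw / abs(ct))
    if abs(st) > 1e-15:
        r = min(r, hh / abs(st))
    return r * ct, r * st


# ---------------------------------------------------------------------------
# main construction
# ---------------------------------------------------------------------------

def build_mesh(plate: PlateSpec, path: CrackPath, params: MeshParams | None = None
               ) -> CrackMesh:
    """Mesh the plate around the incision described by ``path``.

    The incision polyline is resampled with geometric grading toward the tips
    (using the analytic shape carried by the path), so the ``n_segments`` of
    the incoming path only matters for its own inspection exports.
    """
    params = params or MeshParams()
    shape = path.shape
    a = shape.half_length
    r_in = params.resolved_r_inner(a)
    growth = params.ring_growth

    plate.check_incision(shape)

    # --- feasibility of the ring system ---
    r_ring_max = r_in * growth ** (params.n_rings - 1)
    half_chord = chord_span(shape) / 2.0
    tip = shape.point_at(0.0)
    edge_clearance = min(plate.width / 2 - abs(tip[0]), plate.height / 2 - abs(tip[1]))
    if r_ring_max >= half_chord:
        raise MeshError(
            f"outermost ring radius {r_ring_max:.3e} m reaches the other tip "
            f"(half chord {half_chord:.3e} m); reduce r_inner/ring_growth/n_rings"
        )
    if r_ring_max >= edge_clearance:
        raise MeshError(
            f"outermost ring radius {r_ring_max:.3e} m reaches the plate edge "
            f"(clearance {edge_clearance:.3e} m)"
        )

    # --- crack vertices, graded toward the tips ---
    s_verts = _crack_arclengths(a, r_in, growth, params.crack_spacing_cap_frac,
                                min_half=params.n_rings + 3)
    verts = shape.point_at(s_verts)
    m = len(s_verts) - 1  # segments; even, midpoint at m//2
    assert m % 2 == 0

    y_tip = verts[0, 1]
    c = verts[-1, 0]  # half chord (tips at +-c by symmetry)

    # deviation of the crack from the chord, as a function of arc length
    def deviation(s_crack: float) -> np.ndarray:
        p = shape.point_at(s_crack)
        xc = -c + (s_crack / (2 * a)) * 2 * c
        return p - np.array([xc, y_tip])

    # chord x-positions of the crack vertices (arc-length proportional)
    x_chord = -c + (s_verts / (2 * a)) * 2 * c

    # --- layer radius / blend schedule ---
    hw, hh = plate.width / 2.0, plate.height / 2.0
    r_half = min(hw, hh)
    ts = [r_in * growth**k for k in range(params.n_rings)]
    t = ts[-1]
    while True:
        t = min(t * params.outer_growth, t + params.far_field_size)
        if t >= 0.55 * r_half:
            break
        ts.append(t)
    t_b0 = ts[-1]
    # the stadium's x-extent is c + t: end the schedule at r_half - c so every
    # pre-final layer stays strictly inside the plate (the final layer is the
    # exact square regardless)
    r_end = max(1.05 * t_b0, r_half - c)
    blend_ts = np.geomspace(t_b0, r_end, params.n_blend + 1)[1:]
    us = [0.0] * len(ts) + [_smoothstep(j / params.n_blend) for j in range(1, params.n_blend + 1)]
    us[-1] = 1.0
    ts = ts + list(blend_ts)
    K = len(ts)  # layers 1..K (layer 0 is the crack)

    n_c = params.n_spokes

    # --- canonical slot order (clockwise from top center) ---
    # upper x >= 0 (crack vertex m/2 .. m), right cap (1..n_c-1), lower
    # right -> left (vertex m .. 0), left cap (1..n_c-1), upper x < 0
    # (vertex 0 .. m/2 - 1)
    slots = []  # (kind, index) with kind in {"up", "rcap", "lo", "lcap"}
    for j in range(m // 2, m + 1):
        slots.append(("up", j))
    for k in range(1, n_c):
        slots.append(("rcap", k))
    for j in range(m, -1, -1):
        slots.append(("lo", j))
    for k in range(1, n_c):
        slots.append(("lcap", k))
    for j in range(0, m // 2):
        slots.append(("up", j))
    N = len(slots)
    assert N == 2 * m + 2 * n_c

    # decay of the crack's chord-deviation with offset distance; the Gaussian
    # form keeps 1 - w = O(t^2) so the innermost layers stay parallel to the
    # crack faces even for strongly kinked chevrons
    def dev_weight(tk: float) -> float:
        return math.exp(-4.0 * (tk / a) ** 2)

    def baseline_arc(kind: str, idx: int, st: _Stadium) -> float:
        c_, cap = st.c, st.cap
        if kind == "up":
            x = x_chord[idx]
            return x % st.L  # maps negative x to the trailing top segment
        if kind == "rcap":
            return c_ + cap * idx / n_c
        if kind == "lo":
            return c_ + cap + (c_ - x_chord[idx])
        return 3 * c_ + cap + cap * idx / n_c  # lcap

    # --- nodes ---
    coords: list[np.ndarray] = []
    layer_ids: list[np.ndarray] = []

    # layer 0: crack nodes; seam pairs duplicated, tips single
    up_ids = np.arange(0, m + 1)
    coords.extend(verts)
    lo_ids = np.empty(m + 1, dtype=int)
    lo_ids[0], lo_ids[m] = up_ids[0], up_ids[m]
    nid = m + 1
    for j in range(1, m):
        coords.append(verts[j].copy())
        lo_ids[j] = nid
        nid += 1
    slot_ids0 = np.empty(N, dtype=int)
    for i, (kind, idx) in enumerate(slots):
        if kind == "up":
            slot_ids0[i] = up_ids[idx]
        elif kind == "lo":
            slot_ids0[i] = lo_ids[idx]
        elif kind == "rcap":
            slot_ids0[i] = up_ids[m]
        else:
            slot_ids0[i] = up_ids[0]
    layer_ids.append(slot_ids0)

    # layers 1..K
    for k in range(K):
        tk, uk = ts[k], us[k]
        st = _Stadium(c, y_tip, tk)
        w = dev_weight(tk)
        ids_k = np.arange(nid, nid + N)
        nid += N
        pts = np.empty((N, 2))
        for i, (kind, idx) in enumerate(slots):
            arc = baseline_arc(kind, idx, st)
            if i and arc < 1e-12:  # wrapped to 0: canonical order means arc L
                arc = st.L
            p = np.array(st.point(arc))
            flat, xf, _ = st.on_flat(arc)
            if flat and w > 1e-12:
                s_crack = (xf + c) * a / c
                p = p + w * deviation(min(max(s_crack, 0.0), 2 * a))
            if uk > 0.0:
                theta = math.atan2(p[1], p[0])
                q = np.array(_square_radial(theta, hw, hh))
                p = (1.0 - uk) * p + uk * q
            pts[i] = p
        coords.extend(pts)
        layer_ids.append(ids_k)

    nodes = np.array(coords)

    # snap the outermost layer's nearest nodes onto the plate corners
    outer = layer_ids[-1]
    for cx, cy in ((hw, hh), (-hw, hh), (-hw, -hh), (hw, -hh)):
        d = np.linalg.norm(nodes[outer] - np.array([cx, cy]), axis=1)
        nodes[outer[np.argmin(d)]] = (cx, cy)

    # --- elements ---
    tris: list[tuple[int, int, int]] = []
    quads: list[tuple[int, int, int, int]] = []
    for k in range(K):
        A = layer_ids[k]
        B = layer_ids[k + 1]
        for i in range(N):
            i2 = (i + 1) % N
            a0, a1, b1, b0 = A[i], A[i2], B[i2], B[i]
            if a0 == a1:
                tris.append((a0, b1, b0))
            else:
                quads.append((a0, a1, b1, b0))
    tris_a = np.array(tris, dtype=int)
    quads_a = np.array(quads, dtype=int)

    # the construction orients all elements the same way; a mixed-sign area
    # pattern means tangled layers (a genuine error), a uniformly negative one
    # just means the traversal was clockwise -- flip globally
    sa_t = np.empty(0)
    if len(tris_a):
        p = nodes[tris_a]
        sa_t = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    sa_q = np.empty(0)
    if len(quads_a):
        p = nodes[quads_a]
        sa_q = 0.5 * (_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
                      + _cross2(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    sa = np.concatenate([sa_t, sa_q])
    if np.any(sa > 0) and np.any(sa < 0):
        raise MeshError(
            f"tangled layers: {np.sum(sa < 0)} of {len(sa)} elements inverted"
        )
    if np.all(sa < 0):
        if len(tris_a):
            tris_a = tris_a[:, ::-1].copy()
        if len(quads_a):
            quads_a = quads_a[:, ::-1].copy()

    # --- seam bookkeeping ---
    seam_pairs = np.stack([up_ids[1:m], lo_ids[1:m]], axis=1)
    seg = np.diff(verts, axis=0)
    seg /= np.linalg.norm(seg, axis=1, keepdims=True)
    seg_n = np.stack([-seg[:, 1], seg[:, 0]], axis=1)  # left normal = up
    vn = seg_n[:-1] + seg_n[1:]
    vn /= np.linalg.norm(vn, axis=1, keepdims=True)
    seam_normals = vn  # for interior vertices 1..m-1
    seam_arclengths = s_verts[1:m]
    midpoint_pair = (int(up_ids[m // 2]), int(lo_ids[m // 2]))

    tip_nodes = {"left": int(up_ids[0]), "right": int(up_ids[m])}
    tip_extension = {k: np.asarray(v, dtype=float)
                     for k, v in path.tip_tangents.items()}

    # --- boundary edges with side tags ---
    boundary_edges: dict[str, list[tuple[int, int]]] = {
        "left": [], "right": [], "top": [], "bottom": []}
    for i in range(N):
        n1, n2 = int(outer[i]), int(outer[(i + 1) % N])
        mx, my = (nodes[n1] + nodes[n2]) / 2.0
        dists = {"right": abs(mx - hw), "left": abs(mx + hw),
                 "top": abs(my - hh), "bottom": abs(my + hh)}
        boundary_edges[min(dists, key=dists.get)].append((n1, n2))
    boundary_edges_a = {k: np.array(v, dtype=int).reshape(-1, 2)
                        for k, v in boundary_edges.items()}

    mesh = CrackMesh(
        nodes=nodes,
        tris=tris_a,
        quads=quads_a,
        seam_pairs=seam_pairs,
        seam_normals=seam_normals,
        seam_arclengths=seam_arclengths,
        midpoint_pair=midpoint_pair,
        tip_nodes=tip_nodes,
        tip_extension=tip_extension,
        tip_rings={},
        boundary_edges=boundary_edges_a,
        plate=plate,
        path=path,
        params=params,
    )

    mesh.tip_rings = {side: _grow_rings(mesh, tip_nodes[side], params.n_rings)
                      for side in ("left", "right")}

    _check_jacobians(mesh)
    return mesh


def _grow_rings(mesh: CrackMesh, tip_node: int, n_rings: int) -> list[np.ndarray]:
    """Contour rings by node-connectivity growth from the tip node.

    Ring 1 = all elements containing the tip node; ring k = elements sharing
    at least one node with rings < k, not already assigned.  Growth never
    crosses the seam because the faces carry distinct node ids.
    """
    node_to_elems: dict[int, list[int]] = {}
    for eid, conn in mesh.iter_elements():
        for n in conn:
            node_to_elems.setdefault(int(n), []).append(eid)

    assigned: set[int] = set()
    frontier_nodes = {tip_node}
    rings = []
    for _ in range(n_rings):
        ring = set()
        for n in frontier_nodes:
            for eid in node_to_elems.get(n, ()):
                if eid not in assigned:
                    ring.add(eid)
        assigned |= ring
        frontier_nodes = {int(n) for eid in ring for n in mesh.element_nodes(eid)}
        rings.append(np.array(sorted(ring), dtype=int))
    return rings


def _check_jacobians(mesh: CrackMesh) -> None:
    areas = mesh.element_areas()
    if np.any(areas <= 0):
        bad = np.where(areas <= 0)[0]
        raise MeshError(f"{len(bad)} element(s) with non-positive area, e.g. ids {bad[:5]}")
    # bilinear quads: corner Jacobians must all be positive (no bow ties);
    # for a CCW convex corner, cross(edge to next, edge to prev) > 0
    if len(mesh.quads):
        p = mesh.nodes[mesh.quads]
        for i in range(4):
            v1 = p[:, (i + 1) % 4] - p[:, i]
            v2 = p[:, (i - 1) % 4] - p[:, i]
            cr = _cross2(v1, v2)
            if np.any(cr <= 0):
                bad = np.where(cr <= 0)[0]
                raise MeshError(
                    f"{len(bad)} quad(s) with non-positive corner Jacobian "
                    f"(first ids {bad[:5]})"
                )


# ---------------------------------------------------------------------------
# seam-aware cleanup operations
# ---------------------------------------------------------------------------

def snap_seam_nodes(mesh: CrackMesh, path: CrackPath, snap_tol: float = 1e-8,
                    merge_tol: float = 1e-10) -> CrackMesh:
    """Project stray nodes onto the incision and merge near-duplicates.

    Nodes (other than seam-face nodes and tips) lying within ``snap_tol`` of
    the incision are projected onto it; non-seam node pairs closer than
    ``merge_tol`` are merged.  A well-formed mesh is returned unchanged
    (idempotent).  Merging that would collapse an element raises
    :class:`MeshError`.
    """
    out = mesh.copy()
    shape = path.shape
    s_dense = np.linspace(0.0, shape.total_length, 4097)
    dense = shape.point_at(s_dense)

    seam_nodes = set(map(int, out.seam_pairs.ravel()))
    seam_nodes |= set(out.tip_nodes.values())

    from scipy.spatial import cKDTree

    tree = cKDTree(dense)
    d, idx = tree.query(out.nodes)
    # vertex distance overestimates the path distance by up to the dense
    # sampling step: shortlist generously, then project exactly
    ds = shape.total_length / (len(s_dense) - 1)
    for n in np.where(d < snap_tol + ds)[0]:
        if int(n) in seam_nodes:
            continue
        proj = _project_to_polyline(out.nodes[n], dense, idx[n])
        if np.linalg.norm(proj - out.nodes[n]) < snap_tol:
            out.nodes[n] = proj

    # merge non-seam near-coincident nodes
    pairs = cKDTree(out.nodes).query_pairs(merge_tol, output_type="ndarray")
    remap = np.arange(out.n_nodes)
    seam_pair_set = {tuple(sorted(p)) for p in map(tuple, out.seam_pairs)}
    for n1, n2 in pairs:
        n1, n2 = int(min(n1, n2)), int(max(n1, n2))
        if (n1, n2) in seam_pair_set:
            continue
        remap[n2] = n1
    if np.any(remap != np.arange(out.n_nodes)):
        while np.any(remap[remap] != remap):
            remap = remap[remap]
        out.tris = remap[out.tris]
        out.quads = remap[out.quads]
        out.seam_pairs = remap[out.seam_pairs]
        out.midpoint_pair = tuple(int(remap[i]) for i in out.midpoint_pair)
        out.tip_nodes = {k: int(remap[v]) for k, v in out.tip_nodes.items()}
        out.boundary_edges = {k: remap[v] for k, v in out.boundary_edges.items()}
        out.tip_rings = {k: [r.copy() for r in v] for k, v in out.tip_rings.items()}
        # drop now-unused nodes, compacting ids
        used = np.zeros(out.n_nodes, dtype=bool)
        used[out.tris.ravel() if len(out.tris) else []] = True
        if len(out.quads):
            used[out.quads.ravel()] = True
        used[list(out.tip_nodes.values())] = True
        if len(out.seam_pairs):
            used[out.seam_pairs.ravel()] = True
        new_ids = -np.ones(out.n_nodes, dtype=int)
        new_ids[used] = np.arange(used.sum())
        out.nodes = out.nodes[used]
        out.tris = new_ids[out.tris] if len(out.tris) else out.tris
        out.quads = new_ids[out.quads] if len(out.quads) else out.quads
        out.seam_pairs = new_ids[out.seam_pairs] if len(out.seam_pairs) else out.seam_pairs
        out.midpoint_pair = tuple(int(new_ids[i]) for i in out.midpoint_pair)
        out.tip_nodes = {k: int(new_ids[v]) for k, v in out.tip_nodes.items()}
        out.boundary_edges = {k: new_ids[v] for k, v in out.boundary_edges.items()}
        areas = out.element_areas()
        if np.any(np.abs(areas) < 1e-30):
            raise MeshError("node merge collapsed an element to zero area")
        for _, conn in out.iter_elements():
            if len(set(map(int, conn))) != len(conn):
                raise MeshError("node merge collapsed an element edge "
                                "(repeated node id)")
    return out


def _project_to_polyline(p: np.ndarray, poly: np.ndarray, hint: int) -> np.ndarray:
    lo, hi = max(hint - 2, 0), min(hint + 2, len(poly) - 1)
    best, bd = p, math.inf
    for i in range(lo, hi):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        tt = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
        q = a + tt * ab
        d = float(np.linalg.norm(p - q))
        if d < bd:
            best, bd = q, d
    return best


def merge_seam(mesh: CrackMesh) -> CrackMesh:
    """Collapse all seam pairs, producing the equivalent *uncracked* plate.

    Used for patch tests and homogeneous-reference solves.  The result keeps
    the node count (orphaned lower-face ids simply become unreferenced) and
    carries ``has_seam=False``; contour-integral evaluation refuses it.
    """
    out = mesh.copy()
    remap = np.arange(out.n_nodes)
    for up, lo in out.seam_pairs:
        remap[int(lo)] = int(up)
    out.tris = remap[out.tris] if len(out.tris) else out.tris
    out.quads = remap[out.quads] if len(out.quads) else out.quads
    out.seam_pairs = np.empty((0, 2), dtype=int)
    out.has_seam = False
    return out
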