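"""Polygonal chains, triangle meshes, and puncture detection.

Every structural element is abstracted to a polygonal chain through selected
backbone atoms (default P and C4') plus, at each closing base pair, the
center-of-mass pseudoatoms of the two paired nucleobases.  Closed chains are
covered with a triangle mesh (centroid fan refined by recursive longest-edge
midpoint subdivision); punctures are segment-triangle intersections found
with the Moller-Trumbore algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _chemistry as chem
from .elements import StructuralElement
from .structure_io import NucleotideResidue, StructureModel, global_residue_order


class GeometryError(Exception):
    pass


class DegenerateMeshError(GeometryError):
    pass


@dataclass
class GeometryConfig:
    """Numerical tolerances of the geometric stage (Angstrom)."""

    mesh_edge_target: float = 2.0
    mesh_max_depth: int = 8
    mt_eps_det: float = 1e-9
    mt_eps_bary: float = 1e-7
    merge_radius: float = 0.05
    overlap_threshold: float = 0.2
    com_mass_weighted: bool = False


# unified atomic masses for the optional mass-weighted base COM
_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def base_center_of_mass(res: NucleotideResidue, mass_weighted: bool = False) -> np.ndarray:
    """Pseudoatom at the nucleobase ring center (unweighted centroid by
    default; mass-weighted variant by config)."""
    names = chem.RING_ATOMS.get(res.parent or "", None)
    if names is None:
        names = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
    pts, weights = [], []
    for n in names:
        if res.has(n):
            pts.append(res.coord(n))
            weights.append(_MASS.get(res.atoms[n].element.upper(), 12.0))
    if not pts:
        raise GeometryError(f"residue {res.label}: no base ring atoms for COM")
    pts = np.array(pts)
    if mass_weighted:
        w = np.array(weights)
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    return pts.mean(axis=0)


@dataclass
class PolygonalChain:
    element_id: str
    points: np.ndarray  # (n, 3)
    point_sources: list[tuple[int, str]]  # (global residue index, atom name or 'base-COM')
    closed: bool

    @property
    def n_points(self) -> int:
        return len(self.points)

    def segments(self):
        """Yield (a, b, source_a, source_b) for every chain segment."""
        n = self.n_points
        last = n if self.closed else n - 1
        for t in range(last):
            u = (t + 1) % n
            yield self.points[t], self.points[u], self.point_sources[t], self.point_sources[u]


def build_polygonal_chain(
    element: StructuralElement,
    model: StructureModel,
    atom_selection: tuple[str, ...] = ("P", "C4'"),
    config: GeometryConfig | None = None,
) -> PolygonalChain:
    """Chain for one element.

    Open strands: the selected backbone atoms of each residue, 5'->3'
    (P silently omitted at a chain's 5' terminus).  Closed elements: the same
    backbone points along every strand segment of the boundary, with the two
    base-COM pseudoatoms bridging each closing pair, forming one ring.
    """
    cfg = config or GeometryConfig()
    order = global_residue_order(model)
    res_list = element.residues
    bridge = {frozenset(p.as_tuple) for p in element.closing_pairs}
    points: list[np.ndarray] = []
    sources: list[tuple[int, str]] = []
    n = len(res_list)

    def backbone(idx: int) -> None:
        res = order[idx]
        for name in atom_selection:
            if not res.has(name):
                if name == "P" and res.seq_index == 0:
                    continue  # 5'-terminal residue legitimately lacks P
                raise GeometryError(
                    f"residue {res.label} (chain {res.chain_id}) lacks selected atom {name}"
                )
            points.append(res.coord(name))
            sources.append((idx, name))

    def com(idx: int) -> None:
        res = order[idx]
        points.append(base_center_of_mass(res, cfg.com_mass_weighted))
        sources.append((idx, "base-COM"))

    if element.is_closed:
        for t in range(n):
            cur, prev = res_list[t], res_list[(t - 1) % n]
            nxt = res_list[(t + 1) % n]
            if frozenset((prev, cur)) in bridge:
                com(cur)
            backbone(cur)
            if frozenset((cur, nxt)) in bridge:
                com(cur)
    else:
        for idx in res_list:
            backbone(idx)

    pts = np.array(points, dtype=float)
    if element.is_closed:
        # drop repeated consecutive points (within 1e-6 A), including wrap
        keep = [0]
        for t in range(1, len(pts)):
            if np.linalg.norm(pts[t] - pts[keep[-1]]) > 1e-6:
                keep.append(t)
        if len(keep) > 1 and np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) <= 1e-6:
            keep.pop()
        pts = pts[keep]
        sources = [sources[t] for t in keep]
        if len(pts) < 3:
            raise GeometryError(f"closed chain for {element.element_id} has <3 points")
    else:
        if len(pts) < 2:
            raise GeometryError(f"open chain for {element.element_id} has <2 points")
    return PolygonalChain(
        element_id=element.element_id, points=pts, point_sources=sources,
        closed=element.is_closed,
    )


# ---------------------------------------------------------------------------
# triangulation


@dataclass
class TriangleMesh:
    element_id: str
    vertices: np.ndarray  # (m, 3)
    triangles: np.ndarray  # (k, 3) int
    boundary_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def total_area(self) -> float:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def boundary_cycle(self) -> list[int]:
        """Vertex indices of the (refined) boundary, ordered as a cycle."""
        adj: dict[int, list[int]] = {}
        for a, b in self.boundary_edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        start = 0
        cycle = [start]
        prev = None
        cur = start
        while True:
            nbrs = [x for x in adj[cur] if x != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            if cur == start:
                break
            cycle.append(cur)
        return cycle


def triangulate(chain: PolygonalChain, config: GeometryConfig | None = None) -> TriangleMesh:
    """Cover a closed chain with triangles.

    Centroid-fan construction followed by recursive longest-edge midpoint
    subdivision down to ``mesh_edge_target``, capped at ``mesh_max_depth``
    levels.  Non-planar rings are meshed as-is from the fan.  Boundary edges
    are subdivided consistently so the mesh boundary equals the refined chain.
    """
    cfg = config or GeometryConfig()
    if not chain.closed:
        raise GeometryError("triangulate requires a closed chain")
    pts = chain.points
    n = len(pts)
    if n < 3:
        raise GeometryError("closed chain has <3 points")
    centroid = pts.mean(axis=0)
    # degeneracy: total fan area ~ 0 means all points collinear
    area = 0.0
    for t in range(n):
        area += 0.5 * np.linalg.norm(
            np.cross(pts[t] - centroid, pts[(t + 1) % n] - centroid)
        )
    scale = max(1.0, float(np.abs(pts - centroid).max()))
    if area < 1e-9 * scale * scale:
        raise DegenerateMeshError(
            f"chain for {chain.element_id}: all points collinear, no surface to span"
        )

    vertices: list[np.ndarray] = [p for p in pts] + [centroid]
    c_idx = n
    boundary: set[frozenset] = {frozenset((t, (t + 1) % n)) for t in range(n)}
    midpoint: dict[frozenset, int] = {}

    def mid(a: int, b: int) -> int:
        key = frozenset((a, b))
        m = midpoint.get(key)
        if m is None:
            m = len(vertices)
            vertices.append(0.5 * (vertices[a] + vertices[b]))
            midpoint[key] = m
            if key in boundary:
                boundary.discard(key)
                boundary.add(frozenset((a, m)))
                boundary.add(frozenset((m, b)))
        return m

    final: list[tuple[int, int, int]] = []
    stack: list[tuple[int, int, int, int]] = [
        (t, (t + 1) % n, c_idx, 0) for t in range(n)
    ]
    while stack:
        a, b, c, depth = stack.pop()
        va, vb, vc = vertices[a], vertices[b], vertices[c]
        edges = [
            (float(np.linalg.norm(vb - va)), a, b, c),
            (float(np.linalg.norm(vc - vb)), b, c, a),
            (float(np.linalg.norm(va - vc)), c, a, b),
        ]
        longest = max(edges, key=lambda e: e[0])
        if longest[0] <= cfg.mesh_edge_target or depth >= cfg.mesh_max_depth:
            final.append((a, b, c))
            continue
        _, ea, eb, opp = longest
        m = mid(ea, eb)
        stack.append((ea, m, opp, depth + 1))
        stack.append((m, eb, opp, depth + 1))

    # orient boundary edges along the chain direction
    b_edges: list[tuple[int, int]] = [tuple(sorted(e)) for e in boundary]
    return TriangleMesh(
        element_id=chain.element_id,
        vertices=np.array(vertices),
        triangles=np.array(final, dtype=int),
        boundary_edges=b_edges,
    )


# ---------------------------------------------------------------------------
# segment-triangle intersection (Moller-Trumbore)


def segment_triangle_intersect(
    p0, p1, tri, eps_det: float = 1e-9, eps_bary: float = 1e-7
):
    """Moller-Trumbore for a segment p0->p1 against one triangle.

    Returns the intersection point or None.  Barycentric gates are relaxed
    by ``eps_bary``; segments parallel to the triangle plane (|det| below
    ``eps_det``) never intersect.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v0, v1, v2 = (np.asarray(v, dtype=float) for v in tri)
    d = p1 - p0
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) < eps_det:
        return None
    inv = 1.0 / det
    tvec = p0 - v0
    u = float(np.dot(tvec, pvec)) * inv
    if u < -eps_bary:
        return None
    qvec = np.cross(tvec, e1)
    v = float(np.dot(d, qvec)) * inv
    if v < -eps_bary or u + v > 1.0 + eps_bary:
        return None
    t = float(np.dot(e2, qvec)) * inv
    if t < 0.0 or t > 1.0:
        return None
    return p0 + t * d


def _segment_mesh_hits(p0, p1, vertices, triangles, eps_det=1e-9, eps_bary=1e-7):
    """Vectorized Moller-Trumbore of one segment against all triangles.

    Returns (triangle indices, intersection points)."""
    v0 = vertices[triangles[:, 0]]
    v1 = vertices[triangles[:, 1]]
    v2 = vertices[triangles[:, 2]]
    d = p1 - p0
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(np.broadcast_to(d, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) >= eps_det
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = p0 - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    ok &= u >= -eps_bary
    qvec = np.cross(tvec, e1)
    v = qvec @ d * inv
    ok &= (v >= -eps_bary) & (u + v <= 1.0 + eps_bary)
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    ok &= (t >= 0.0) & (t <= 1.0)
    idx = np.nonzero(ok)[0]
    return idx, p0 + np.outer(t[idx], d)


@dataclass
class Puncture:
    mesh_element: str
    chain_element: str
    point: np.ndarray
    segment: tuple[tuple[int, str], tuple[int, str]]
    triangle_index: int


def count_punctures(
    mesh: TriangleMesh,
    chain: PolygonalChain,
    exclusion: frozenset[int] = frozenset(),
    config: GeometryConfig | None = None,
) -> list[Puncture]:
    """All punctures of ``chain`` through ``mesh``.

    Segments with an endpoint in a residue of the meshed element
    (``exclusion``) are skipped; hits within ``merge_radius`` of each other
    collapse to one crossing; crossings whose segment endpoint lies within
    ``overlap_threshold`` of any mesh vertex are discarded as
    overlapping-atom artifacts.
    """
    cfg = config or GeometryConfig()
    tree = cKDTree(mesh.vertices)
    raw: list[Puncture] = []
    for a, b, src_a, src_b in chain.segments():
        if src_a[0] in exclusion or src_b[0] in exclusion:
            continue
        idx, pts = _segment_mesh_hits(
            a, b, mesh.vertices, mesh.triangles, cfg.mt_eps_det, cfg.mt_eps_bary
        )
        if len(idx) == 0:
            continue
        d_a = tree.query(a)[0]
        d_b = tree.query(b)[0]
        if min(d_a, d_b) < cfg.overlap_threshold:
            continue
        for tri_idx, point in zip(idx, pts):
            raw.append(Puncture(
                mesh_element=mesh.element_id,
                chain_element=chain.element_id,
                point=point,
                segment=(src_a, src_b),
                triangle_index=int(tri_idx),
            ))
    # deduplicate: one geometric crossing -> one puncture
    accepted: list[Puncture] = []
    for hit in raw:
        if all(np.linalg.norm(hit.point - h.point) > cfg.merge_radius for h in accepted):
            accepted.append(hit)
    return accepted
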