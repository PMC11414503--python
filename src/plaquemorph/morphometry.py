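"""Per-plaque geometric parameters measured on reconstructed surfaces.

For each plaque the parameter set is: volume, surface area, length (the
straight-line distance between the proximal and distal end points), surface
distance (the shortest on-surface path between those ends), the area and
maximal chord (diameter) of the largest cross-section cut perpendicular to
the local artery centreline, the upstream and downstream arc lengths from
the ends to that largest section and their ratio (a longitudinal-asymmetry
index), and the volume/surface-area ratio (VSAR, units mm — r/3 for a
sphere of radius r). Calcifications, being geometrically irregular, get
volume and surface area only.

Proximal/distal follows the centreline's point order, which the caller
fixes in the flow direction (common carotid -> internal carotid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .image import BinaryMask
from .reconstruction import TriSurface, mesh_area, mesh_volume

__all__ = [
    "Centreline",
    "PlaqueMetrics",
    "CalcificationMetrics",
    "compute_centreline",
    "find_endpoints",
    "plaque_length",
    "surface_distance",
    "cross_sections",
    "largest_cross_section",
    "ud_lengths",
    "measure_plaque",
]

METRIC_COLUMNS = [
    "volume_mm3",
    "surface_area_mm2",
    "length_mm",
    "surface_distance_mm",
    "max_cross_area_mm2",
    "max_cross_diameter_mm",
    "upstream_mm",
    "downstream_mm",
    "ud_ratio",
    "vsar_mm",
]


@dataclass
class Centreline:
    """Ordered proximal->distal polyline of the artery axis, in mm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centreline points must be (n, 3)")
        if self.points.shape[0] < 2:
            raise ValueError("centreline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centreline has duplicate consecutive points")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the polyline at arc-length coordinate s."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arclength, s, side="right")) - 1
        i = min(i, self.points.shape[0] - 2)
        t = (s - self.arclength[i]) / (self.arclength[i + 1] - self.arclength[i])
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent at arc-length s (segment direction)."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arclength, s, side="right")) - 1
        i = min(max(i, 0), self.points.shape[0] - 2)
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arc-length coordinate of the closest centreline point, per point."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        best_d = np.full(pts.shape[0], np.inf)
        best_s = np.zeros(pts.shape[0])
        for i in range(self.points.shape[0] - 1):
            p0, p1 = self.points[i], self.points[i + 1]
            seg = p1 - p0
            L = np.linalg.norm(seg)
            t = np.clip(((pts - p0) @ seg) / (L * L), 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            d = np.linalg.norm(pts - proj, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_s[better] = self.arclength[i] + t[better] * L
        return best_s


@dataclass
class PlaqueMetrics:
    volume: float  # mm^3
    surface_area: float  # mm^2
    length: float  # mm
    surface_distance: float  # mm
    max_cross_area: float  # mm^2
    max_cross_diameter: float  # mm
    upstream_length: float  # mm
    downstream_length: float  # mm
    ud_ratio: float
    vsar: float  # mm

    def as_row(self) -> dict[str, float]:
        return dict(
            zip(
                METRIC_COLUMNS,
                [
                    self.volume,
                    self.surface_area,
                    self.length,
                    self.surface_distance,
                    self.max_cross_area,
                    self.max_cross_diameter,
                    self.upstream_length,
                    self.downstream_length,
                    self.ud_ratio,
                    self.vsar,
                ],
            )
        )


@dataclass
class CalcificationMetrics:
    volume: float  # mm^3
    surface_area: float  # mm^2
    parent_plaque_id: int


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    points = points[keep]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s_new = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(s_new, cum, points[:, d])
    return out


def _skeleton_path(mask: BinaryMask) -> np.ndarray:
    """Distance-transform-weighted ridge path through a tubular mask."""
    import networkx as nx
    from scipy import ndimage
    from skimage.morphology import skeletonize

    struct = ndimage.generate_binary_structure(3, 3)
    _, ncomp = ndimage.label(mask.voxels, structure=struct)
    if ncomp != 1:
        raise ValueError(
            f"lumen mask has {ncomp} connected components; supply an axis "
            "polyline instead"
        )
    skel = skeletonize(mask.voxels)
    coords = np.argwhere(skel)
    if coords.shape[0] < 2:
        raise ValueError("skeleton degenerate; supply an axis polyline")
    index = {tuple(c): i for i, c in enumerate(coords)}
    G = nx.Graph()
    G.add_nodes_from(range(coords.shape[0]))
    offsets = np.array(
        [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
    ) - 1
    spacing = np.asarray(mask.spacing)
    for i, c in enumerate(coords):
        for off in offsets:
            nb = tuple(c + off)
            j = index.get(nb)
            if j is not None and j > i:
                G.add_edge(i, j, weight=float(np.linalg.norm(off * spacing)))
    if not nx.is_connected(G):
        raise ValueError(
            "skeleton is disconnected (looped or branched lumen); supply an "
            "axis polyline"
        )
    # double-sweep: farthest node from an arbitrary node, then farthest from it
    src = 0
    d = nx.single_source_dijkstra_path_length(G, src)
    a = max(d, key=d.get)
    d, paths = nx.single_source_dijkstra(G, a)
    b = max(d, key=d.get)
    path = np.array([coords[i] for i in paths[b]], dtype=float)
    pts = path * spacing + np.asarray(mask.origin)
    # thinning retracts tube ends by about one radius; extend the path along
    # its end tangents until it leaves the mask
    pts = _extend_to_boundary(pts, mask)
    # light moving-average smoothing to damp voxel staircase
    if pts.shape[0] >= 5:
        kernel = np.ones(5) / 5.0
        inner = np.column_stack(
            [np.convolve(pts[:, d], kernel, mode="valid") for d in range(3)]
        )
        pts = np.vstack([pts[:1], inner, pts[-1:]])
    return pts


def _extend_to_boundary(pts: np.ndarray, mask: BinaryMask) -> np.ndarray:
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    shape = np.asarray(mask.shape)

    def inside(p):
        idx = np.round((p - origin) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(mask.voxels[tuple(idx)])

    step = float(spacing.min()) / 2.0
    out = pts
    for end, inner in ((0, min(4, pts.shape[0] - 1)), (-1, max(-5, -pts.shape[0]))):
        d = pts[end] - pts[inner]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        p = pts[end].copy()
        last = p.copy()
        for _ in range(int(4 * max(shape))):
            p = p + step * d
            if not inside(p):
                break
            last = p.copy()
        if end == 0:
            out = np.vstack([last, out])
        else:
            out = np.vstack([out, last])
    return out


def compute_centreline(
    lumen_mask: BinaryMask | None = None,
    axis: np.ndarray | None = None,
    step: float = 0.5,
) -> Centreline:
    """Artery centreline from a supplied axis polyline or a lumen mask.

    A supplied polyline is resampled at uniform *step* mm and returned; a
    mask is skeletonized and the longest ridge path between the two
    farthest skeleton endpoints is extracted and smoothed.
    """
    if axis is not None:
        pts = np.asarray(axis, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("axis must be an (n>=2, 3) polyline")
        return Centreline(_resample_polyline(pts, step))
    if lumen_mask is None:
        raise ValueError("provide either a lumen mask or an axis polyline")
    return Centreline(_resample_polyline(_skeleton_path(lumen_mask), step))


def find_endpoints(m: TriSurface, c: Centreline) -> tuple[int, int]:
    """Vertex indices of the proximal and distal plaque ends.

    Each vertex is projected to its nearest centreline arc-length
    coordinate; the vertices attaining the minimal and maximal coordinate
    are the proximal and distal ends (ties -> smallest vertex index).
    """
    if c.length <= 0:
        raise ValueError("degenerate centreline")
    s = c.project(m.vertices)
    return int(np.argmin(s)), int(np.argmax(s))


def plaque_length(m: TriSurface, proximal: int, distal: int) -> float:
    """Euclidean distance between the two end vertices, in mm."""
    return float(np.linalg.norm(m.vertices[proximal] - m.vertices[distal]))


def _augmented_graph(m: TriSurface):
    """Edge graph of the mesh plus one round of edge-midpoint Steiner points.

    Returns (sparse weight matrix, total node count). Vertices keep their
    indices; midpoint of unique edge e gets index n_vertices + e.
    """
    v = m.vertices
    f = m.faces
    nv = v.shape[0]
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    nodes = np.vstack([v, mid])
    # per face: 3 vertices + 3 midpoints, connect all 15 pairs
    e01 = inverse[: f.shape[0]] + nv
    e12 = inverse[f.shape[0] : 2 * f.shape[0]] + nv
    e20 = inverse[2 * f.shape[0] :] + nv
    hexes = np.column_stack([f[:, 0], f[:, 1], f[:, 2], e01, e12, e20])
    pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
    rows, cols = [], []
    for i, j in pairs:
        rows.append(hexes[:, i])
        cols.append(hexes[:, j])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    # edges shared by adjacent faces appear twice; deduplicate so sparse
    # construction cannot sum their weights
    canon = np.column_stack([np.minimum(rows, cols), np.maximum(rows, cols)])
    canon = np.unique(canon, axis=0)
    rows, cols = canon[:, 0], canon[:, 1]
    w = np.linalg.norm(nodes[rows] - nodes[cols], axis=1)
    n = nodes.shape[0]
    W = coo_matrix((w, (rows, cols)), shape=(n, n))
    return (W + W.T).tocsr(), n


def surface_distance(m: TriSurface, proximal: int, distal: int) -> float:
    """Shortest on-surface path length (mm) between the two end vertices.

    Approximated by Dijkstra on the mesh edge graph augmented with one
    level of edge-midpoint Steiner points; always >= the Euclidean chord.
    """
    W, _ = _augmented_graph(m)
    d = dijkstra(W, directed=False, indices=proximal)
    out = float(d[distal])
    if not np.isfinite(out):
        raise ValueError("mesh is disconnected between the two endpoints")
    return out


def _section_area_diameter(m: TriSurface, origin, normal):
    """(area, diameter) of the mesh's planar section, or None if empty."""
    sec = m.mesh.section(plane_origin=origin, plane_normal=normal)
    if sec is None or len(sec.entities) == 0:
        return None
    planar, to_3d = sec.to_2D()
    area = float(abs(planar.area))
    pts2 = np.asarray(planar.vertices)
    if pts2.shape[0] < 2:
        return None
    if pts2.shape[0] > 8:
        try:
            from scipy.spatial import ConvexHull

            # max chord is attained on the convex hull of the section points
            pts2 = pts2[ConvexHull(pts2).vertices]
        except Exception:
            pass
    diff = pts2[:, None, :] - pts2[None, :, :]
    diam = float(np.sqrt((diff**2).sum(-1)).max())
    return area, diam


def cross_sections(
    m: TriSurface, c: Centreline, step: float = 0.5
) -> list[tuple[float, float, float]]:
    """Plaque cross-sections perpendicular to the centreline.

    At each arc-length sample the plane through the centreline point with
    normal along the local tangent cuts the mesh; returns
    ``(arc_position, area_mm2, diameter_mm)`` per non-empty section.
    """
    if not m.is_watertight:
        raise ValueError("cross-sections require a watertight mesh")
    out = []
    for s in np.arange(0.0, c.length + step / 2, step):
        s = min(s, c.length)
        res = _section_area_diameter(m, c.point_at(s), c.tangent_at(s))
        if res is not None and res[0] > 0:
            out.append((float(s), res[0], res[1]))
    return out


def largest_cross_section(
    sections: list[tuple[float, float, float]],
    m: TriSurface | None = None,
    c: Centreline | None = None,
    step: float = 0.5,
) -> tuple[float, float, float]:
    """Section with maximal area (ties -> smallest arc position).

    If the mesh and centreline are supplied, the discrete argmax is refined
    by golden-section search over +/- one sampling step.
    """
    if not sections:
        raise ValueError("no cross-sections to maximize over")
    areas = [a for _, a, _ in sections]
    k = int(np.argmax(areas))  # argmax returns the first (smallest s) on ties
    s0, a0, d0 = sections[k]
    if m is None or c is None:
        return s0, a0, d0

    def neg_area(s):
        res = _section_area_diameter(m, c.point_at(s), c.tangent_at(s))
        return -(res[0] if res else 0.0)

    lo, hi = max(0.0, s0 - step), min(c.length, s0 + step)
    opt = minimize_scalar(neg_area, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    if -opt.fun > a0:
        res = _section_area_diameter(m, c.point_at(opt.x), c.tangent_at(opt.x))
        if res is not None:
            return float(opt.x), res[0], res[1]
    return s0, a0, d0


def ud_lengths(
    s_proximal: float, s_distal: float, s_section: float
) -> tuple[float, float]:
    """Upstream and downstream arc lengths around the largest section.

    Upstream runs from the proximal end's centreline projection to the
    section, downstream from the section to the distal projection; the
    reported asymmetry ratio is upstream/downstream.
    """
    if not (s_proximal - 1e-9 <= s_section <= s_distal + 1e-9):
        raise ValueError(
            f"largest section at s={s_section:.3f} lies outside the endpoint "
            f"span [{s_proximal:.3f}, {s_distal:.3f}]"
        )
    up = max(s_section - s_proximal, 0.0)
    down = max(s_distal - s_section, 0.0)
    return float(up), float(down)


def measure_plaque(
    mesh: TriSurface,
    calcification_meshes: list[TriSurface],
    centreline: Centreline,
    step: float = 0.5,
    min_calc_volume: float = 1.0,
    plaque_id: int = 1,
) -> tuple[PlaqueMetrics, list[CalcificationMetrics]]:
    """Full parameter vector for one plaque plus its calcifications.

    Calcifications below ``min_calc_volume`` mm^3 are dropped (the same
    exclusion rule as for plaques).
    """
    vol = mesh_volume(mesh)
    area = mesh_area(mesh)
    prox, dist = find_endpoints(mesh, centreline)
    s_all = centreline.project(mesh.vertices)
    s_prox, s_dist = float(s_all[prox]), float(s_all[dist])
    length = plaque_length(mesh, prox, dist)
    geod = surface_distance(mesh, prox, dist)
    secs = cross_sections(mesh, centreline, step=step)
    if not secs:
        raise ValueError("no centreline-perpendicular plane intersects the plaque")
    # restrict to the endpoint span before maximizing
    in_span = [sec for sec in secs if s_prox - step <= sec[0] <= s_dist + step]
    s_max, max_area, max_diam = largest_cross_section(
        in_span or secs, mesh, centreline, step=step
    )
    s_max = float(np.clip(s_max, s_prox, s_dist))
    up, down = ud_lengths(s_prox, s_dist, s_max)
    ratio = up / down if down > 0 else np.inf
    metrics = PlaqueMetrics(
        volume=vol,
        surface_area=area,
        length=length,
        surface_distance=geod,
        max_cross_area=max_area,
        max_cross_diameter=max_diam,
        upstream_length=up,
        downstream_length=down,
        ud_ratio=ratio,
        vsar=vol / area,
    )
    calcs = []
    for cm in calcification_meshes:
        cv = mesh_volume(cm)
        if cv < min_calc_volume:
            continue
        calcs.append(
            CalcificationMetrics(
                volume=cv, surface_area=mesh_area(cm), parent_plaque_id=plaque_id
            )
        )
    return metrics, calcs
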