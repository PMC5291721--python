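"""Remeshing of the deformed cell domain with field transfer.

The moving Lagrangian cell mesh is periodically rebuilt over its current
boundary polygon. Nodal fields transfer by piecewise-linear interpolation
(exact for linear fields), element fields by sampling the old
piecewise-constant field at new element centroids.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .mesh import MeshingError, TriMesh, _signed_areas


def mesh_polygon(boundary_pts: np.ndarray, target_edge_length: float) -> TriMesh:
    """Mesh the interior of a simple polygon.

    The boundary is resampled at the target spacing; interior nodes come
    from a triangular lattice clipped away from the boundary, and the
    triangulation is a Delaunay of the union restricted to the polygon.
    """
    poly = Polygon(boundary_pts)
    if not poly.is_valid:
        # repair small self-intersections (local boundary folds)
        fixed = poly.buffer(0)
        if fixed.geom_type == "MultiPolygon":
            fixed = max(fixed.geoms, key=lambda g: g.area)
        poly = fixed
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("invalid boundary polygon for remeshing")
    h = target_edge_length
    ring = poly.exterior
    n_b = max(8, int(round(ring.length / h)))
    s = ring.length * np.arange(n_b) / n_b
    bpts = np.array([ring.interpolate(d).coords[0] for d in s])

    minx, miny, maxx, maxy = poly.bounds
    dx, dy = h, h * np.sqrt(3) / 2
    ys = np.arange(miny + 0.5 * dy, maxy, dy)
    pts = []
    for k, y in enumerate(ys):
        off = 0.25 * dx if k % 2 else -0.25 * dx
        xs = np.arange(minx + 0.5 * dx + off, maxx, dx)
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    interior = np.vstack(pts) if pts else np.zeros((0, 2))
    if len(interior):
        keep = shapely.contains_xy(poly.buffer(-0.55 * h), interior[:, 0], interior[:, 1])
        interior = interior[keep]

    nodes = np.vstack([bpts, interior])
    try:
        tri = Delaunay(nodes)
    except Exception as exc:  # pragma: no cover
        raise MeshingError(f"remesh triangulation failed: {exc}") from exc
    simplices = tri.simplices
    cent = nodes[simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    areas = np.abs(_signed_areas(nodes, simplices))
    simplices = simplices[inside & (areas > 1e-10 * poly.area)]
    # drop nodes that lost all triangles (can happen for clipped hull slivers)
    used = np.unique(simplices)
    if len(used) < len(nodes):
        remap = -np.ones(len(nodes), dtype=np.int64)
        remap[used] = np.arange(len(used))
        nodes = nodes[used]
        simplices = remap[simplices]
        boundary = remap[np.arange(n_b)]
        if np.any(boundary < 0):
            raise MeshingError("boundary node dropped during remeshing")
    else:
        boundary = np.arange(n_b)
    return TriMesh(nodes, simplices, boundary)


def transfer_nodal_field(old: TriMesh, values: np.ndarray, new: TriMesh) -> np.ndarray:
    """Linear interpolation of a nodal field onto new node positions."""
    return old.interpolate(np.asarray(values), new.nodes, strict=False)


def transfer_element_field(old: TriMesh, values: np.ndarray, new: TriMesh) -> np.ndarray:
    """Sample an old piecewise-constant element field at new centroids."""
    cent = new.centroids
    tri_idx = old.find_triangles(cent)
    missing = tri_idx < 0
    if np.any(missing):
        tree = cKDTree(old.centroids)
        _, nearest = tree.query(cent[missing])
        tri_idx[missing] = nearest
    return np.asarray(values)[tri_idx]


def remesh_and_transfer(
    old: TriMesh,
    nodal_fields: dict,
    element_fields: dict,
    target_edge_length: float,
):
    """Rebuild the mesh over the current boundary and transfer all fields.

    Returns (new_mesh, nodal_fields', element_fields'). Spring anchors are
    re-localized separately (see :meth:`fasim.adhesions.SpringSet.relocalize`).
    """
    new = mesh_polygon(old.nodes[old.boundary], target_edge_length)
    if abs(new.total_area - old.total_area) > 0.02 * old.total_area:
        warnings.warn(
            f"remeshing changed area by "
            f"{abs(new.total_area - old.total_area) / old.total_area:.2%}"
        )
    nodal = {k: transfer_nodal_field(old, v, new) for k, v in nodal_fields.items()}
    elem = {k: transfer_element_field(old, v, new) for k, v in element_fields.items()}
    return new, nodal, elem
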