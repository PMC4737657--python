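"""Geometric measurements on tagged spine meshes and vesicle clouds.

Implements the measurement conventions of 3DEM spine volumetry:

* head and whole-spine volumes as the volume of the convex hull of a
  tagged region, optionally clipped to the closed dendrite surface;
* region surface areas as sums of tagged triangle areas;
* neck volume by subtraction (whole − head);
* docked-vesicle counts by the 100-nm center-to-active-zone distance rule;
* PSD centroid distances; and replicate measurement error (SEM).

Meshes are in µm; vesicle centers in nm (converted internally, factor
1e-3 µm/nm).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import (ConsistencyError, DomainError, GeometryError,
                     InsufficientDataError, UnitError)
from .mesh import TaggedMesh
from .records import MeasurementReplicates, VesicleCloud

__all__ = [
    "region_hull_volume",
    "region_area",
    "neck_volume",
    "count_docked",
    "point_triangle_distances",
    "min_distance_to_region",
    "psd_centroid_distance",
    "region_centroid",
    "measurement_error",
    "points_in_mesh",
    "NM_PER_UM",
]

NM_PER_UM = 1000.0


# ---------------------------------------------------------------------------
# volumes and areas


def region_hull_volume(mesh: TaggedMesh, region: str, *, clip: bool = False,
                       grid_resolution: int = 24) -> float:
    """Volume (µm³) of the convex hull of a tagged region's vertices.

    With ``clip=True`` the hull is intersected with the closed mesh interior
    by signed-distance (winding-number) sampling on a fixed lattice of
    ``grid_resolution**3`` points spanning the hull — a robust stand-in for
    an exact Boolean intersection. For convex regions of a convex mesh the
    clip is a no-op.
    """
    mesh.require_watertight()
    verts = mesh.region_vertices(region)
    if verts.shape[0] < 4:
        raise GeometryError(
            f"region {region!r} has only {verts.shape[0]} vertices; "
            "a hull volume needs >=4 non-coplanar points")
    try:
        hull = ConvexHull(verts)
    except QhullError as exc:
        raise GeometryError(
            f"region {region!r} is degenerate (coplanar or collinear): {exc}") from exc
    volume = float(hull.volume)
    if not clip:
        return volume

    lo, hi = verts.min(axis=0), verts.max(axis=0)
    axes = [np.linspace(lo[k], hi[k], grid_resolution) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # keep lattice points interior to the hull (strict, to dodge boundary ties)
    inside_hull = np.all(
        grid @ hull.equations[:, :3].T + hull.equations[:, 3] < -1e-12, axis=1)
    pts = grid[inside_hull]
    if pts.shape[0] == 0:
        return volume
    inside_mesh = points_in_mesh(pts, mesh)
    return volume * inside_mesh.mean()


def region_area(mesh: TaggedMesh, region: str) -> float:
    """Sum of triangle areas (µm²) in a tagged region; empty region -> 0."""
    faces = mesh.region_faces(region)
    if faces.size == 0:
        return 0.0
    return float(mesh.mesh.area_faces[faces].sum())


def neck_volume(whole: float, head: float, *, rtol: float = 1e-9) -> float:
    """Neck volume by subtraction: whole-spine volume minus head volume (µm³)."""
    if whole < head * (1 - rtol):
        raise ConsistencyError(
            f"whole-spine volume {whole} < head volume {head}: "
            "head/whole segmentation is inconsistent")
    return max(whole - head, 0.0)


# ---------------------------------------------------------------------------
# point–mesh geometry (numpy, exact; meshes here are small)


def point_triangle_distances(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each point to each triangle.

    ``points``: (n, 3); ``triangles``: (m, 3, 3). Returns (n, m).

    The closest point on a triangle is either the orthogonal projection onto
    its plane (when the projection falls inside) or the closest point on one
    of its three edges; both cases are evaluated and the minimum taken.
    """
    P = np.asarray(points, float).reshape(-1, 3)[:, None, :]       # (n,1,3)
    A = np.asarray(triangles, float)[None, :, 0, :]                # (1,m,3)
    B = np.asarray(triangles, float)[None, :, 1, :]
    C = np.asarray(triangles, float)[None, :, 2, :]

    # edge distances: point-segment for AB, BC, CA
    def seg_dist2(S, E):
        d = E - S
        denom = np.einsum("...k,...k", d, d)
        t = np.einsum("...k,...k", P - S, d) / np.where(denom > 0, denom, 1.0)
        t = np.clip(t, 0.0, 1.0)
        closest = S + t[..., None] * d
        diff = P - closest
        return np.einsum("...k,...k", diff, diff)

    d2 = np.minimum(seg_dist2(A, B), np.minimum(seg_dist2(B, C), seg_dist2(C, A)))

    # interior projection
    n = np.cross(B - A, C - A)                                      # (1,m,3)
    nn = np.einsum("...k,...k", n, n)
    valid = nn > 0
    unit_n = n / np.sqrt(np.where(valid, nn, 1.0))[..., None]
    dist_plane = np.einsum("...k,...k", P - A, unit_n)
    foot = P - dist_plane[..., None] * unit_n
    # barycentric inside test for the foot point
    v0, v1, v2 = C - A, B - A, foot - A
    d00 = np.einsum("...k,...k", v0, v0)
    d01 = np.einsum("...k,...k", v0, v1)
    d11 = np.einsum("...k,...k", v1, v1)
    d20 = np.einsum("...k,...k", v2, v0)
    d21 = np.einsum("...k,...k", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    u = (d11 * d20 - d01 * d21) / denom
    v = (d00 * d21 - d01 * d20) / denom
    inside = valid & (u >= 0) & (v >= 0) & (u + v <= 1)
    d2 = np.where(inside, np.minimum(d2, dist_plane ** 2), d2)
    return np.sqrt(d2)


def min_distance_to_region(points_um: np.ndarray, mesh: TaggedMesh,
                           region: str) -> np.ndarray:
    """Min distance (µm) from each point (µm) to a tagged region's triangles."""
    tris = mesh.region_triangles(region)
    pts = np.asarray(points_um, float).reshape(-1, 3)
    if pts.shape[0] == 0:
        return np.zeros(0)
    # chunk points to bound memory on large clouds
    out = np.empty(pts.shape[0])
    step = max(1, int(2e6 // max(len(tris), 1)))
    for i in range(0, pts.shape[0], step):
        out[i:i + step] = point_triangle_distances(pts[i:i + step], tris).min(axis=1)
    return out


def count_docked(cloud: VesicleCloud, mesh: TaggedMesh, threshold_nm: float = 100.0) -> int:
    """Number of vesicle centers within ``threshold_nm`` of the active zone.

    The distance rule is closed (``<= threshold``). Vesicle coordinates are
    nm, the mesh µm; a sanity check rejects clouds whose extent suggests the
    wrong unit by six orders of magnitude.
    """
    if threshold_nm < 0:
        raise DomainError("threshold_nm must be >= 0")
    if len(cloud) == 0:
        return 0
    span = np.ptp(cloud.centers_nm, axis=0).max()
    mesh_span = np.ptp(mesh.mesh.vertices, axis=0).max()
    if span > 0 and mesh_span > 0 and span < mesh_span:
        # a cloud covering less than the mesh's µm extent in "nm" is suspect
        raise UnitError(
            "vesicle cloud extent is smaller in nm than the mesh extent in µm; "
            "coordinates appear not to be in nm")
    dists_um = min_distance_to_region(cloud.centers_nm / NM_PER_UM, mesh, "active_zone")
    return int(np.sum(dists_um * NM_PER_UM <= threshold_nm))


def points_in_mesh(points: np.ndarray, mesh: TaggedMesh) -> np.ndarray:
    """Boolean inside test for a watertight mesh via generalized winding number."""
    mesh.require_watertight()
    pts = np.asarray(points, float).reshape(-1, 3)
    tris = mesh.mesh.triangles
    out = np.empty(pts.shape[0], dtype=bool)
    step = max(1, int(2e6 // max(len(tris), 1)))
    for i in range(0, pts.shape[0], step):
        out[i:i + step] = _winding_number(pts[i:i + step], tris) > 0.5
    return out


def _winding_number(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    # Van Oosterom & Strackee signed solid angle, summed over triangles / 4π
    a = triangles[None, :, 0, :] - points[:, None, :]
    b = triangles[None, :, 1, :] - points[:, None, :]
    c = triangles[None, :, 2, :] - points[:, None, :]
    la = np.linalg.norm(a, axis=-1)
    lb = np.linalg.norm(b, axis=-1)
    lc = np.linalg.norm(c, axis=-1)
    numer = np.einsum("nmk,nmk->nm", a, np.cross(b, c))
    denom = (la * lb * lc + np.einsum("nmk,nmk->nm", a, b) * lc
             + np.einsum("nmk,nmk->nm", b, c) * la
             + np.einsum("nmk,nmk->nm", a, c) * lb)
    omega = 2.0 * np.arctan2(numer, denom)
    return np.abs(omega.sum(axis=1)) / (4.0 * np.pi)


# ---------------------------------------------------------------------------
# centroids and measurement error


def region_centroid(mesh: TaggedMesh, region: str) -> np.ndarray:
    """Area-weighted centroid (µm) of a tagged region's triangles."""
    faces = mesh.region_faces(region)
    if faces.size == 0:
        raise GeometryError(f"region {region!r} is empty; centroid undefined")
    tris = mesh.mesh.triangles[faces]
    centers = tris.mean(axis=1)
    areas = mesh.mesh.area_faces[faces]
    if areas.sum() == 0:
        raise GeometryError(f"region {region!r} has zero total area")
    return np.average(centers, axis=0, weights=areas)


def psd_centroid_distance(mesh_a: TaggedMesh, mesh_b: TaggedMesh) -> float:
    """Euclidean distance (µm) between the PSD centroids of two spines."""
    ca = region_centroid(mesh_a, "psd")
    cb = region_centroid(mesh_b, "psd")
    return float(np.linalg.norm(ca - cb))


def measurement_error(replicates: MeasurementReplicates) -> dict[str, float]:
    """Replicate measurement error: SEM = sd/√k and SEM relative to the mean."""
    replicates.validate()
    vals = np.asarray(replicates.head_volume_measurements, float)
    k = vals.size
    sem = float(vals.std(ddof=1) / np.sqrt(k))
    return {"sem": sem, "relative_sem": sem / float(vals.mean())}
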