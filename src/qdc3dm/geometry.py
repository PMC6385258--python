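"""Membrane-surface reconstruction and ligand internalization scoring.

The cell membrane is reconstructed from a membrane-stain point cloud as a
3D alpha shape: keep the Delaunay tetrahedra whose circumradius is at
most the alpha radius and take the boundary triangles of that complex.
For each ligand spot a ray is cast from the nucleus centroid through the
spot; the ratio of the spot's distance to the distance of the (outermost)
surface crossing is the relative radial distance rho, and spots with
rho <= 0.8 are classified internalized.  The internalized fraction
weights each spot by its calibrated QD count.

Axial anisotropy: z coordinates are converted into xy-pixel units via
``z_scale = z_spacing / pixel_size`` before any metric computation, so
the alpha radius is an isotropic length in pixel units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

__all__ = [
    "MembraneSurface",
    "InternalizationResult",
    "build_surface",
    "relative_distance",
    "internalized_fraction",
    "membrane_accuracy",
    "register_and_project",
    "INTERNALIZATION_THRESHOLD",
]

INTERNALIZATION_THRESHOLD = 0.8
DEFAULT_ALPHA = 50.0


@dataclass
class MembraneSurface:
    """Alpha-shape boundary of a membrane point cloud (scaled coordinates)."""

    vertices: np.ndarray  # (n, 3), z already in xy-pixel units
    boundary_facets: np.ndarray  # (m, 3) vertex indices
    alpha_radius: float
    z_scale: float = 1.0
    volume: float = 0.0
    is_closed: bool = field(default=False)

    def facet_coords(self) -> np.ndarray:
        return self.vertices[self.boundary_facets]  # (m, 3, 3)


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized linear solve)."""
    p = points[simplices]  # (n, 4, 3)
    a = p[:, 1:] - p[:, :1]  # (n, 3, 3) edge matrix
    b = 0.5 * (p[:, 1:] ** 2 - p[:, :1] ** 2).sum(axis=2)  # (n, 3)
    radii = np.full(len(simplices), np.inf)
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - p[ok, 0], axis=1)
    return radii


def build_surface(
    points: np.ndarray,
    alpha_radius: float = DEFAULT_ALPHA,
    z_scale: float = 1.0,
) -> MembraneSurface:
    """Alpha-shape surface of a 3D point cloud.

    ``points`` are (x, y, z) with z in plane units; ``z_scale`` converts
    planes to xy-pixel units so that ``alpha_radius`` is isotropic.
    Tetrahedra with circumradius <= alpha are kept; boundary triangles are
    the faces belonging to exactly one kept tetrahedron.
    """
    pts = np.asarray(points, dtype=float).copy()
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 points in 3D")
    pts[:, 2] *= z_scale
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 3:
        raise ValueError("points are coplanar; no 3D surface exists")
    tri = Delaunay(pts)
    radii = _circumradii(pts, tri.simplices)
    kept = tri.simplices[radii <= alpha_radius]
    if len(kept) == 0:
        raise ValueError("alpha radius too small: empty alpha complex")
    # boundary faces: appear in exactly one kept tetrahedron
    faces = np.concatenate(
        [kept[:, [0, 1, 2]], kept[:, [0, 1, 3]], kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]
    )
    faces_sorted = np.sort(faces, axis=1)
    _, idx, counts = np.unique(
        faces_sorted, axis=0, return_index=True, return_counts=True
    )
    boundary = faces_sorted[idx[counts == 1]]
    # closedness: every boundary edge shared by exactly two boundary facets
    edges = np.sort(
        np.concatenate([boundary[:, [0, 1]], boundary[:, [0, 2]], boundary[:, [1, 2]]]),
        axis=1,
    )
    _, ecounts = np.unique(edges, axis=0, return_counts=True)
    closed = bool(len(boundary) > 0 and np.all(ecounts == 2))
    # alpha-complex volume
    tet = pts[kept]
    vol = float(np.abs(np.linalg.det(tet[:, 1:] - tet[:, :1])).sum() / 6.0)
    return MembraneSurface(
        vertices=pts,
        boundary_facets=boundary,
        alpha_radius=alpha_radius,
        z_scale=z_scale,
        volume=vol,
        is_closed=closed,
    )


def _ray_facet_ts(
    origin: np.ndarray, direction: np.ndarray, facets: np.ndarray
) -> np.ndarray:
    """Moller-Trumbore ray/triangle intersection distances (t > 0 only)."""
    v0 = facets[:, 0]
    e1 = facets[:, 1] - v0
    e2 = facets[:, 2] - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    ts = np.full(len(facets), np.nan)
    if not ok.any():
        return ts[~np.isnan(ts)]
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin[None, :] - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9) & (t > 1e-9)
    return t[hit]


def relative_distance(
    spot: np.ndarray,
    nucleus: np.ndarray,
    surface: MembraneSurface,
) -> float:
    """Relative radial distance rho of a spot from the nucleus.

    A ray is cast from the nucleus through the spot and intersected with
    the boundary facets; the outermost crossing defines the surface point,
    and rho = |spot - nucleus| / |surf - nucleus|.  Spot/nucleus are
    (x, y, z-plane); z is scaled by the surface's ``z_scale``.  Returns
    NaN (unresolved) when the ray exits an open surface without crossing.
    """
    sp = np.asarray(spot, dtype=float).copy()
    nu = np.asarray(nucleus, dtype=float).copy()
    sp[2] *= surface.z_scale
    nu[2] *= surface.z_scale
    d = sp - nu
    dist = np.linalg.norm(d)
    if dist == 0.0:
        return 0.0
    d = d / dist
    ts = _ray_facet_ts(nu, d, surface.facet_coords())
    if len(ts) == 0:
        return float("nan")
    t_surf = float(np.max(ts))
    return float(dist / t_surf)


@dataclass
class InternalizationResult:
    rho: np.ndarray
    internalized: np.ndarray  # bool per spot
    fraction: float
    nucleus: tuple[float, float, float]
    n_unresolved: int = 0


def internalized_fraction(
    rho: np.ndarray,
    n_qd: np.ndarray | None = None,
    nucleus: tuple[float, float, float] = (0.0, 0.0, 0.0),
    threshold: float = INTERNALIZATION_THRESHOLD,
) -> InternalizationResult:
    """Calibrated-count-weighted fraction of spots with rho <= threshold.

    ``n_qd`` weights each spot by its QD content (defaults to 1 per
    spot); unresolved spots (NaN rho) are excluded from both numerator
    and denominator and reported.
    """
    rho = np.asarray(rho, dtype=float)
    if n_qd is None:
        n_qd = np.ones_like(rho)
    n_qd = np.asarray(n_qd, dtype=float)
    ok = np.isfinite(rho)
    total = float(n_qd[ok].sum())
    if total <= 0:
        raise ValueError("no resolved spots with positive QD weight")
    internal = ok & (rho <= threshold)
    frac = float(n_qd[internal].sum() / total)
    return InternalizationResult(
        rho=rho,
        internalized=internal,
        fraction=frac,
        nucleus=tuple(float(v) for v in nucleus),
        n_unresolved=int((~ok).sum()),
    )


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Unsigned distance from one point to each triangle (vectorized)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    # interior projection
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    closest = a + v[:, None] * ab + w[:, None] * ac
    # vertex regions
    closest = np.where((d1 <= 0)[:, None] & (d2 <= 0)[:, None], a, closest)
    closest = np.where((d3 >= 0)[:, None] & (d4 <= d3)[:, None], b, closest)
    closest = np.where((d6 >= 0)[:, None] & (d5 <= d6)[:, None], c, closest)
    # edge AB
    vab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0), 0, 1)
    on_ab = (d1 >= 0) & (d3 <= 0) & (vc <= 0)
    closest = np.where(on_ab[:, None], a + vab[:, None] * ab, closest)
    # edge AC
    vac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0), 0, 1)
    on_ac = (d2 >= 0) & (d6 <= 0) & (vb <= 0)
    closest = np.where(on_ac[:, None], a + vac[:, None] * ac, closest)
    # edge BC
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    vbc = np.clip(np.where(den != 0, num / np.where(den != 0, den, 1.0), 0), 0, 1)
    on_bc = ((d4 - d3) >= 0) & ((d5 - d6) >= 0) & (va <= 0)
    closest = np.where(on_bc[:, None], b + vbc[:, None] * (c - b), closest)
    return np.linalg.norm(p[None, :] - closest, axis=1)


def membrane_accuracy(
    surface: MembraneSurface, reference_points: np.ndarray
) -> dict:
    """Distance of each reference point to the reconstructed surface.

    Reference points are (x, y, z-plane); z is scaled like the surface.
    Returns per-point distances plus mean/max summaries.
    """
    ref = np.asarray(reference_points, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference point cloud")
    ref = ref.copy()
    ref[:, 2] *= surface.z_scale
    tri = surface.facet_coords()
    dists = np.array([_point_triangle_distance(p, tri).min() for p in ref])
    return {
        "distances": dists,
        "mean": float(dists.mean()),
        "max": float(dists.max()),
        "table": np.column_stack([ref, dists]),
    }


# ---------------------------------------------------------------------------
# pattern registration and localization projections


def _mask_frame(mask: np.ndarray):
    """Centroid and principal-axis angle of a binary mask."""
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    x, y = xs - cx, ys - cy
    cov = np.array([[np.mean(x * x), np.mean(x * y)], [np.mean(x * y), np.mean(y * y)]])
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, np.argmax(vals)]
    angle = float(np.arctan2(major[1], major[0]))
    return np.array([cx, cy]), angle


def _rotate_mask(mask: np.ndarray, center: np.ndarray, angle: float, out_shape, out_center):
    """Nearest-neighbour resample of mask rotated by ``angle`` about center."""
    ny, nx = out_shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dx, dy = xx - out_center[0], yy - out_center[1]
    ca, sa = np.cos(-angle), np.sin(-angle)
    sx = center[0] + ca * dx - sa * dy
    sy = center[1] + sa * dx + ca * dy
    return ndimage.map_coordinates(
        mask.astype(float), [sy, sx], order=0, mode="constant"
    ).astype(bool)


def register_and_project(
    cells: list[tuple[np.ndarray, np.ndarray]],
    bins_2d: int = 64,
    bins_1d: int = 64,
    min_overlap: float = 0.8,
) -> dict:
    """Align adhesion-pattern masks and pool spot localizations.

    Each cell is ``(pattern_mask, spot_xy)``.  Masks are rigidly aligned
    to the first cell's mask by centroid translation and principal-axis
    rotation; the 180-degree ambiguity is resolved by maximizing mask
    overlap.  Spots are transformed identically and pooled into a 2D
    occupancy map over the reference pattern and a 1D histogram along the
    pattern's long axis.  Cells whose aligned mask overlaps the reference
    by less than ``min_overlap`` (intersection / reference area) are
    excluded with a warning.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    ref_mask = np.asarray(cells[0][0], dtype=bool)
    ref_center, ref_angle = _mask_frame(ref_mask)
    all_xy = []
    transforms = []
    included = []
    for i, (mask, spots) in enumerate(cells):
        mask = np.asarray(mask, dtype=bool)
        center, angle = _mask_frame(mask)
        best = None
        for extra in (0.0, np.pi):
            rot = ref_angle - angle + extra
            aligned = _rotate_mask(mask, center, -rot, ref_mask.shape, ref_center)
            overlap = (aligned & ref_mask).sum() / max(ref_mask.sum(), 1)
            if best is None or overlap > best[0]:
                best = (overlap, rot)
        overlap, rot = best
        if overlap < min_overlap:
            warnings.warn(
                f"cell {i}: aligned pattern overlap {overlap:.2f} < {min_overlap}; excluded",
                stacklevel=2,
            )
            included.append(False)
            transforms.append({"rotation": rot, "overlap": overlap})
            continue
        included.append(True)
        transforms.append({"rotation": rot, "overlap": overlap})
        xy = np.asarray(spots, dtype=float)[:, :2]
        ca, sa = np.cos(rot), np.sin(rot)
        rel = xy - center[None, :]
        rotated = np.column_stack(
            [ca * rel[:, 0] - sa * rel[:, 1], sa * rel[:, 0] + ca * rel[:, 1]]
        )
        all_xy.append(rotated + ref_center[None, :])
    pooled = np.concatenate(all_xy, axis=0) if all_xy else np.empty((0, 2))
    ny, nx = ref_mask.shape
    heat, xe, ye = np.histogram2d(
        pooled[:, 0], pooled[:, 1], bins=bins_2d, range=[[0, nx], [0, ny]]
    )
    hist1d, edges1d = np.histogram(pooled[:, 0], bins=bins_1d, range=(0, nx))
    return {
        "heatmap": heat,
        "heatmap_edges": (xe, ye),
        "hist1d": hist1d,
        "hist1d_edges": edges1d,
        "pooled_xy": pooled,
        "transforms": transforms,
        "included": included,
    }
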