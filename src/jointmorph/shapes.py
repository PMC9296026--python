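"""Average joint geometry from aligned specimen surface meshes.

Aligned half-jaw surfaces are cut into transversal (constant-z) slices; each
slice yields a closed outline which is resampled to a fixed number of points
by normalised arc length from a common dorsal anchor, so outlines from
different specimens correspond point-by-point and can be averaged
point-wise. The stack of averaged outlines is then voxelised back into a
labelled tetrahedral simulation domain, with the interzone added as the
volume filling the gap between the two joint elements and hypertrophic
bands labelled beyond a stated distance from the joint line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import LineString, Point, Polygon

from .meshing import VolumeMesh, loft_outline_stack


@dataclass
class SliceOutline:
    """Closed outline of one transversal slice.

    ``z`` is the plane position along the slicing axis (μm) and ``points``
    an (N, 2) array tracing a simple closed polygon counter-clockwise in the
    (x, y) plane; the first point is anchored at the dorsal (+y) crossing of
    the outline.
    """

    z: float
    points: np.ndarray

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


def _largest_polygon(segments_2d: np.ndarray) -> Polygon | None:
    if len(segments_2d) == 0:
        return None
    path = trimesh.load_path(segments_2d)
    polys = list(path.polygons_full)
    if not polys:
        return None
    return max(polys, key=lambda p: p.area)


def resample_outline(polygon: Polygon, n_points: int = 128) -> np.ndarray:
    """Resample a polygon boundary to n points by arc length.

    The boundary is oriented counter-clockwise and the start anchored where
    the ray from the centroid towards +y (dorsal) crosses it, giving
    consistent point correspondence across specimens.
    """
    ring = polygon.exterior
    if not ring.is_ccw:
        ring = LineString(list(ring.coords)[::-1])
    c = polygon.centroid
    span = max(polygon.bounds[3] - polygon.bounds[1], 1.0)
    ray = LineString([(c.x, c.y), (c.x, c.y + 10 * span)])
    hit = ring.intersection(ray)
    if hit.is_empty:
        anchor_s = 0.0
    else:
        pts = (
            [hit] if isinstance(hit, Point) else list(getattr(hit, "geoms", [hit]))
        )
        pts = [p for p in pts if isinstance(p, Point)]
        anchor = min(pts, key=lambda p: p.y) if pts else Point(ring.coords[0])
        anchor_s = ring.project(anchor)
    total = ring.length
    s = (anchor_s + np.arange(n_points) / n_points * total) % total
    out = np.array([[ring.interpolate(si).x, ring.interpolate(si).y] for si in s])
    return out


def slice_mesh(
    mesh: trimesh.Trimesh,
    spacing: float = 5.0,
    axis: int = 2,
    n_points: int = 128,
) -> list[SliceOutline]:
    """Cut a watertight surface into transversal outlines.

    One outline per occupied plane at the given spacing along the slicing
    axis (default z, anteroposterior); slices with several components keep
    the largest polygon (rudiment cross-sections are simply connected).
    """
    if axis != 2:
        raise NotImplementedError("transversal (z) slicing only")
    lo, hi = mesh.bounds[:, axis]
    heights = np.arange(lo + spacing / 2, hi, spacing)
    if len(heights) == 0:
        heights = np.array([(lo + hi) / 2])
    origin = np.zeros(3)
    normal = np.zeros(3)
    normal[axis] = 1.0
    sections, _, _ = trimesh.intersections.mesh_multiplane(
        mesh, origin, normal, heights
    )
    outlines = []
    for z, seg in zip(heights, sections):
        poly = _largest_polygon(seg)
        if poly is None or poly.area <= 0:
            continue
        outlines.append(SliceOutline(z=float(z), points=resample_outline(poly, n_points)))
    return outlines


def average_outlines(outlines: list[SliceOutline]) -> SliceOutline:
    """Point-wise mean outline of K corresponding specimen outlines.

    All outlines must be resampled to the same N; correspondence is by the
    shared arc-length/anchor convention of :func:`resample_outline`.
    Averaging K copies of one outline returns that outline (idempotence).
    """
    if not outlines:
        raise ValueError("need at least one outline")
    n = {o.points.shape for o in outlines}
    if len(n) != 1:
        raise ValueError("outlines must share the same resampling N")
    pts = np.mean([o.points for o in outlines], axis=0)
    z = float(np.mean([o.z for o in outlines]))
    return SliceOutline(z=z, points=pts)


def average_outline_stacks(
    stacks: list[list[SliceOutline]], tol: float = 1e-6
) -> list[SliceOutline]:
    """Average several specimens' outline stacks plane by plane.

    Planes are matched by z position; a plane missing in some specimens is
    averaged over the specimens present there.
    """
    planes: dict[float, list[SliceOutline]] = {}
    for stack in stacks:
        for o in stack:
            key = round(o.z / tol) * tol if tol else o.z
            planes.setdefault(key, []).append(o)
    return [average_outlines(v) for _, v in sorted(planes.items())]


@dataclass
class InterzoneSpec:
    """Parametric interzone: fills the z-gap between the two rudiments.

    The external boundary of the interzone is not inferred from data; its
    cross-section is the point-wise average of the two facing rudiment
    outlines.
    """

    z_range: tuple[float, float]


def reconstruct_and_mesh(
    outline_stacks: dict[str, list[SliceOutline]],
    interzone: InterzoneSpec,
    hypertrophic_offset: float = 30.0,
    n_rings: int = 3,
    interzone_planes: int = 2,
) -> VolumeMesh:
    """Loft averaged outline stacks into a labelled simulation mesh.

    The MC (anterior) and PQ (posterior) averaged outline stacks are joined
    into one column: across the interzone gap the cross-section blends
    linearly from the last MC outline to the first PQ outline, so the
    interzone fills the gap and is conformally attached to both rudiments.
    Hypertrophic bands are labelled beyond ``hypertrophic_offset`` μm from
    the joint line. Consecutive outlines must overlap in the transversal
    plane (a loft through non-overlapping outlines would self-intersect).

    Parameters
    ----------
    outline_stacks : dict with keys "MC" and "PQ" mapping to averaged
        outline stacks ordered along z, all resampled to a common N.
    interzone : gap specification between the two rudiments.
    n_rings : radial resolution of the lofted cross-section mesh.
    interzone_planes : number of interior planes inserted across the gap.
    """
    for key in ("MC", "PQ"):
        if not outline_stacks.get(key):
            raise ValueError(f"missing outline stack for {key}")
    mc = sorted(outline_stacks["MC"], key=lambda o: o.z)
    pq = sorted(outline_stacks["PQ"], key=lambda o: o.z)
    z_lo, z_hi = interzone.z_range
    if not (mc[-1].z <= z_lo < z_hi <= pq[0].z):
        raise ValueError("interzone must bound the MC–PQ gap")
    for stack in (mc, pq):
        for a, b in zip(stack, stack[1:]):
            if not a.polygon.intersects(b.polygon):
                raise ValueError(
                    "consecutive outlines do not overlap; cannot loft"
                )

    planes: list[tuple[float, np.ndarray]] = [(o.z, o.points) for o in mc]
    gap_z = np.linspace(z_lo, z_hi, interzone_planes + 2)
    for z in gap_z:
        if z <= mc[-1].z or z >= pq[0].z:
            continue
        f = (z - mc[-1].z) / (pq[0].z - mc[-1].z)
        planes.append((float(z), (1 - f) * mc[-1].points + f * pq[0].points))
    planes.extend((o.z, o.points) for o in pq)

    def region_of_z(z: float) -> str:
        if z < z_lo:
            return "MC_hypertrophic" if z < z_lo - hypertrophic_offset else "MC"
        if z > z_hi:
            return "PQ_hypertrophic" if z > z_hi + hypertrophic_offset else "PQ"
        return "interzone"

    return loft_outline_stack(planes, region_of_z, n_rings=n_rings)
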