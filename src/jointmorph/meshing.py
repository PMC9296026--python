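"""Labelled tetrahedral meshes on a structured voxel lattice.

The simulation domain (two cartilage rudiments, the interzone between them,
hypertrophic bands and the ceratohyal) is represented as a conforming
4-node tetrahedral mesh whose elements each carry exactly one region label.
Meshes are built by sampling a region-indicator function on a cubic voxel
lattice and splitting every occupied voxel into six tetrahedra with the
Freudenthal (Kuhn) triangulation, which is conforming across voxel faces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import trimesh

#: Canonical region labels, in the order used for integer codes.
REGIONS = (
    "MC",
    "PQ",
    "ceratohyal",
    "interzone",
    "MC_hypertrophic",
    "PQ_hypertrophic",
)
REGION_CODE = {name: i for i, name in enumerate(REGIONS)}

#: Regions forming each anatomical rudiment (proliferative + hypertrophic).
RUDIMENT_REGIONS = {
    "MC": ("MC", "MC_hypertrophic"),
    "PQ": ("PQ", "PQ_hypertrophic"),
}

# Freudenthal split: six tets per cube, one per permutation of the axes,
# all sharing the main diagonal corner(0,0,0) -> corner(1,1,1).
_CUBE_TETS = []
for perm in itertools.permutations(range(3)):
    corners = [np.zeros(3, dtype=int)]
    c = np.zeros(3, dtype=int)
    for ax in perm:
        c = c.copy()
        c[ax] = 1
        corners.append(c)
    _CUBE_TETS.append(np.array(corners))


@dataclass
class VolumeMesh:
    """Region-labelled tetrahedral mesh (coordinates in μm).

    Attributes
    ----------
    nodes : (n_nodes, 3) float array
    tets : (n_tets, 4) int array, positively oriented
    region : (n_tets,) int array of codes into :data:`REGIONS`
    voxel_size : lattice pitch used to build the mesh, if applicable
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    voxel_size: float | None = None
    region_names: tuple[str, ...] = field(default=REGIONS)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=int)
        self.region = np.asarray(self.region, dtype=int)
        if self.tets.shape[0] != self.region.shape[0]:
            raise ValueError("one region label per element required")

    # -- geometry ---------------------------------------------------------

    def element_matrices(self) -> np.ndarray:
        """Edge matrices ``[p1-p0, p2-p0, p3-p0]`` per element, (n, 3, 3)."""
        p = self.nodes[self.tets]
        return np.stack([p[:, i] - p[:, 0] for i in (1, 2, 3)], axis=2)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (μm³); all positive for a valid mesh."""
        return np.linalg.det(self.element_matrices()) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def region_mask(self, *names: str) -> np.ndarray:
        codes = [REGION_CODE[n] for n in names]
        return np.isin(self.region, codes)

    def region_volume(self, *names: str) -> float:
        return float(self.volumes()[self.region_mask(*names)].sum())

    def rudiment_mask(self, rudiment: str) -> np.ndarray:
        return self.region_mask(*RUDIMENT_REGIONS[rudiment])

    def rudiment_nodes(self, rudiment: str) -> np.ndarray:
        """Coordinates of all nodes belonging to a rudiment's elements."""
        idx = np.unique(self.tets[self.rudiment_mask(rudiment)])
        return self.nodes[idx]

    def copy(self) -> "VolumeMesh":
        return VolumeMesh(
            self.nodes.copy(), self.tets.copy(), self.region.copy(), self.voxel_size
        )

    # -- surfaces ---------------------------------------------------------

    def boundary_surface(self, mask: np.ndarray | None = None) -> trimesh.Trimesh:
        """Extract the boundary triangle surface of (a subset of) the mesh.

        Faces appearing in exactly one tet of the selection are boundary
        faces; they are oriented outward and returned as a
        :class:`trimesh.Trimesh`.
        """
        tets = self.tets if mask is None else self.tets[mask]
        # Local face order chosen so each face's outward normal is consistent
        # with a positively oriented tet.
        face_local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        faces = tets[:, face_local].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        boundary = faces[counts[inv] == 1]
        return trimesh.Trimesh(
            vertices=self.nodes.copy(), faces=boundary, process=False
        )

    def rudiment_surface(self, rudiment: str) -> trimesh.Trimesh:
        surf = self.boundary_surface(self.rudiment_mask(rudiment))
        surf.remove_unreferenced_vertices()
        return surf

    # -- I/O --------------------------------------------------------------

    def write_vtk(self, path) -> None:
        """Write legacy-ASCII VTK with the region label as cell data."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\njointmorph mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {len(self.nodes)} double\n")
            for p in self.nodes:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            n = len(self.tets)
            fh.write(f"CELLS {n} {5 * n}\n")
            for t in self.tets:
                fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            fh.write(f"CELL_TYPES {n}\n")
            fh.write("\n".join(["10"] * n) + "\n")
            fh.write(f"CELL_DATA {n}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(r) for r in self.region) + "\n")


def _split_wedge(w: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a 6-node wedge into three tets with lattice-consistent diagonals.

    ``w`` holds global node ids: bottom triangle (0,1,2), top (3,4,5) with
    vertical edges 0-3, 1-4, 2-5. Quad-face diagonals are chosen through the
    smallest global id of each face, so neighbouring wedges sharing a quad
    agree and the mesh stays conforming (Dompierre-style rule).
    """
    # rotate so the smallest id sits at bottom vertex 0
    rot = int(np.argmin(w[:3]))
    order = [rot, (rot + 1) % 3, (rot + 2) % 3]
    b = [w[i] for i in order]
    t = [w[i + 3] for i in order]
    v0, v1, v2 = b
    v3, v4, v5 = t
    # remaining ambiguous quad (v1, v2, v5, v4): diagonal through min id
    if min(v1, v5) < min(v2, v4):
        return [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
    return [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]


def loft_outline_stack(
    planes: list[tuple[float, np.ndarray]],
    region_of_z,
    n_rings: int = 3,
) -> VolumeMesh:
    """Loft a stack of closed cross-section outlines into a labelled tet mesh.

    Parameters
    ----------
    planes : ordered list of ``(z, points)`` with ``points`` an (N, 2) array
        tracing the outline counter-clockwise; every plane must use the same
        N with corresponding point indices (same arc-length/anchor
        convention), and outlines must be star-shaped about their centroid.
    region_of_z : callable mapping the mid-z of a layer to a region name.
    n_rings : radial subdivisions of the cross-section disc mesh.

    Every plane carries the same disc topology (centre node + ``n_rings``
    rings of N nodes, the outer ring exactly on the outline); consecutive
    planes are joined by wedges split into tets with conforming diagonals.
    Cross-section areas — and hence region volumes — are exact up to the
    polygonal approximation of the outline.
    """
    if len(planes) < 2:
        raise ValueError("need at least two planes to loft")
    n = planes[0][1].shape[0]
    for z, pts in planes:
        if pts.shape != (n, 2):
            raise ValueError("all outlines must share the same point count")
    zs = [z for z, _ in planes]
    if not all(b > a for a, b in zip(zs, zs[1:])):
        raise ValueError("planes must be strictly ordered along z")

    m = n_rings
    per_plane = 1 + m * n

    def disc_nodes(z, pts):
        c = pts.mean(axis=0)
        nodes = [np.array([c[0], c[1], z])]
        for j in range(1, m + 1):
            f = j / m
            ring = c + f * (pts - c)
            nodes.extend(np.column_stack([ring, np.full(n, z)]))
        return np.array(nodes)

    nodes = np.vstack([disc_nodes(z, pts) for z, pts in planes])

    # disc triangulation (local indices, CCW outlines -> positive areas)
    tris = []
    for k in range(n):
        tris.append((0, 1 + k, 1 + (k + 1) % n))
    for j in range(1, m):
        lo = 1 + (j - 1) * n
        hi = 1 + j * n
        for k in range(n):
            k2 = (k + 1) % n
            tris.append((lo + k, hi + k, hi + k2))
            tris.append((lo + k, hi + k2, lo + k2))
    tris = np.array(tris, dtype=int)

    tets, regions = [], []
    for layer in range(len(planes) - 1):
        base0 = layer * per_plane
        base1 = (layer + 1) * per_plane
        code = REGION_CODE[region_of_z(0.5 * (zs[layer] + zs[layer + 1]))]
        for tri in tris:
            w = np.array(
                [base0 + tri[0], base0 + tri[1], base0 + tri[2],
                 base1 + tri[0], base1 + tri[1], base1 + tri[2]]
            )
            for tet in _split_wedge(w):
                tets.append(tet)
                regions.append(code)
    mesh = VolumeMesh(np.asarray(nodes), np.array(tets), np.array(regions))
    vols = mesh.volumes()
    flip = vols < 0
    if flip.any():
        mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
    if (mesh.volumes() <= 0).any():
        raise ValueError("degenerate loft (non-star-shaped outline?)")
    return mesh


def _lattice(bounds: np.ndarray, h: float):
    lo = np.floor(bounds[0] / h).astype(int) - 1
    hi = np.ceil(bounds[1] / h).astype(int) + 1
    return lo, hi


def tet_mesh_from_regions(
    region_of_points,
    bounds,
    voxel_size: float = 5.0,
) -> VolumeMesh:
    """Build a labelled tet mesh by voxelising a region-indicator function.

    Parameters
    ----------
    region_of_points : callable
        Vectorised function mapping an (n, 3) array of points to an (n,)
        integer array of region codes, with ``-1`` meaning outside every
        region. Must assign at most one region per point (disjoint regions
        are the caller's contract).
    bounds : (2, 3) array-like
        Axis-aligned bounding box guaranteed to contain all regions.
    voxel_size : float
        Lattice pitch in μm.

    Returns
    -------
    VolumeMesh
        Six positively oriented tets per occupied voxel, labelled by the
        region of the voxel centre.
    """
    h = float(voxel_size)
    if h <= 0:
        raise ValueError("voxel_size must be positive")
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = _lattice(bounds, h)
    nx, ny, nz = hi - lo
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cells = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centres = (cells + 0.5 + lo) * h
    codes = np.asarray(region_of_points(centres))
    keep = codes >= 0
    cells, codes = cells[keep], codes[keep]
    if len(cells) == 0:
        raise ValueError("no voxel centre falls inside any region")

    # Global node ids on the (nx+1, ny+1, nz+1) lattice, compacted.
    def node_id(c):
        return (c[:, 0] * (ny + 1) + c[:, 1]) * (nz + 1) + c[:, 2]

    tets = []
    regions = []
    for local in _CUBE_TETS:
        corner_ids = [node_id(cells + local[v]) for v in range(4)]
        tets.append(np.stack(corner_ids, axis=1))
        regions.append(codes)
    tets = np.concatenate(tets, axis=0)
    regions = np.concatenate(regions)

    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(tets.shape)
    gk = used
    k = gk % (nz + 1)
    j = (gk // (nz + 1)) % (ny + 1)
    i = gk // ((nz + 1) * (ny + 1))
    nodes = (np.stack([i, j, k], axis=1) + lo) * h

    mesh = VolumeMesh(nodes, tets, regions, voxel_size=h)
    vols = mesh.volumes()
    flip = vols < 0
    if flip.any():
        mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
    assert (mesh.volumes() > 0).all()
    return mesh
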