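"""Finite-element growth of a labelled tet mesh by anisotropic eigenstrains.

Growth over a 12-h window is simulated incrementally: in each increment an
element-wise growth eigenstrain

    ε_g = R · diag(g₁, g₂, g₃) · Rᵀ · (Δt / n_increments)

(R the element's local orthonormal growth frame, gᵢ strain rates in h⁻¹) is
applied as a stress-free initial strain in small-strain isotropic linear
elasticity, the displacement field is solved on the current geometry, and
the node coordinates are updated before the next increment. This mirrors an
incremental thermal-expansion-style user-expansion subroutine while staying
fully in-repo: 4-node tetrahedra, sparse assembly, direct solve.

Cartilage is soft (E = 54.8 kPa from nanoindentation of 5-dpf jaw joints,
ν = 0.3); the interzone is two to three orders softer (0.25 % of the
cartilaginous modulus), letting the joint gap comply with the growth of the
opposing elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError, cKDTree

from .growth import GrowthMap, ROIEntry, decompose
from .meshing import REGION_CODE, REGIONS, VolumeMesh

CARTILAGE_E_KPA = 54.8
INTERZONE_E_FRACTION = 0.0025


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (E in kPa)."""

    E: float
    nu: float = 0.3

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    def stiffness_voigt(self) -> np.ndarray:
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3:, 3:] = np.eye(3) * mu
        return D


def default_materials() -> dict[str, Material]:
    cart = Material(E=CARTILAGE_E_KPA, nu=0.3)
    soft = Material(E=CARTILAGE_E_KPA * INTERZONE_E_FRACTION, nu=0.3)
    return {
        "MC": cart,
        "PQ": cart,
        "ceratohyal": cart,
        "MC_hypertrophic": cart,
        "PQ_hypertrophic": cart,
        "interzone": soft,
    }


@dataclass
class BC:
    """One boundary-condition set: nodes with fixed global directions."""

    name: str
    nodes: np.ndarray
    fixed: tuple[bool, bool, bool]

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=int)
        if len(self.nodes) == 0:
            raise ValueError(f"BC set {self.name!r} selects no nodes")


def _end_nodes(mesh: VolumeMesh, mask: np.ndarray, axis: int, end: str) -> np.ndarray:
    idx = np.unique(mesh.tets[mask])
    coord = mesh.nodes[idx, axis]
    tol = (mesh.voxel_size or 1.0) * 0.51
    target = coord.min() if end == "min" else coord.max()
    return idx[np.abs(coord - target) <= tol]


def default_joint_bcs(mesh: VolumeMesh) -> list[BC]:
    """Physiological boundary conditions of the half-jaw model.

    The anterior (low-z) end of the ceratohyal is fixed in all directions;
    the anterior end of the MC is prevented from mediolateral (x)
    translation, maintaining symmetry with the missing half-jaw; the
    posterior end of the PQ is left free only anteroposteriorly (z).
    """
    return [
        BC(
            "ceratohyal_anterior",
            _end_nodes(mesh, mesh.region_mask("ceratohyal"), 2, "min"),
            (True, True, True),
        ),
        BC(
            "mc_anterior",
            _end_nodes(mesh, mesh.rudiment_mask("MC"), 2, "min"),
            (True, False, False),
        ),
        BC(
            "pq_posterior",
            _end_nodes(mesh, mesh.rudiment_mask("PQ"), 2, "max"),
            (True, True, False),
        ),
    ]


def minimal_bcs(mesh: VolumeMesh) -> list[BC]:
    """3-2-1 constraints removing only the six rigid-body modes.

    Picks three mutually distant nodes: one fully fixed, one fixed normal to
    their common line, one fixed out of their common plane. Leaves a
    uniformly growing body stress-free.
    """
    n = mesh.nodes
    a = int(np.argmin(n @ [1, 1, 1]))
    # node along +x from a, at same y,z if possible (structured lattices have one)
    same_yz = np.where(
        (np.abs(n[:, 1] - n[a, 1]) < 1e-9) & (np.abs(n[:, 2] - n[a, 2]) < 1e-9)
    )[0]
    b = int(same_yz[np.argmax(n[same_yz, 0])])
    same_z = np.where(np.abs(n[:, 2] - n[a, 2]) < 1e-9)[0]
    c = int(same_z[np.argmax(n[same_z, 1])])
    return [
        BC("pin", np.array([a]), (True, True, True)),
        BC("slide_x", np.array([b]), (False, True, True)),
        BC("slide_xy", np.array([c]), (False, False, True)),
    ]


@dataclass
class ElementGrowthField:
    """Per-element growth rates and local orthonormal growth frames.

    ``rates[e]`` are (g₁, g₂, g₃) in h⁻¹ along the columns of ``frames[e]``
    (direction 1 = main growth direction, 2 = second, 3 = third).
    """

    rates: np.ndarray
    frames: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if not np.isfinite(self.rates).all():
            raise ValueError("growth rates must be finite")
        err = np.abs(
            np.einsum("eij,eik->ejk", self.frames, self.frames) - np.eye(3)
        ).max()
        if err > 1e-8:
            raise ValueError(f"growth frames not orthonormal (max dev {err:.2e})")

    def eigenstrain_tensors(self) -> np.ndarray:
        """R diag(g) Rᵀ per element, (n, 3, 3), h⁻¹."""
        return np.einsum(
            "eij,ej,ekj->eik", self.frames, self.rates, self.frames
        )


@dataclass
class GrowthStepResult:
    nodes: np.ndarray
    displacement: np.ndarray
    stresses: np.ndarray  # final-increment Voigt stress per element, kPa
    converged: bool
    message: str = "ok"
    increments: int = 0

    def von_mises(self) -> np.ndarray:
        s = self.stresses
        sx, sy, sz, txy, tyz, txz = s.T
        return np.sqrt(
            0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
            + 3 * (txy**2 + tyz**2 + txz**2)
        )


# ---------------------------------------------------------------------------
# assembly


def _element_b_matrices(nodes: np.ndarray, tets: np.ndarray):
    p = nodes[tets]
    Dm = np.stack([p[:, i] - p[:, 0] for i in (1, 2, 3)], axis=2)
    vol = np.linalg.det(Dm) / 6.0
    if (vol <= 0).any():
        raise FloatingPointError("inverted element encountered")
    inv = np.linalg.inv(Dm)
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = inv  # rows of Dm⁻¹ are ∇λ_i
    grads[:, 0, :] = -inv.sum(axis=1)
    B = np.zeros((len(tets), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def _tensor_to_voigt_strain(eps: np.ndarray) -> np.ndarray:
    """(n,3,3) strain tensors → (n,6) Voigt with engineering shears."""
    return np.stack(
        [
            eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
            2 * eps[:, 0, 1], 2 * eps[:, 1, 2], 2 * eps[:, 0, 2],
        ],
        axis=1,
    )


def _region_stiffness(mesh: VolumeMesh, materials: dict[str, Material]) -> np.ndarray:
    D_by_code = {}
    for name, mat in materials.items():
        D_by_code[REGION_CODE[name]] = mat.stiffness_voigt()
    missing = set(np.unique(mesh.region)) - set(D_by_code)
    if missing:
        names = [REGIONS[m] for m in missing]
        raise ValueError(f"no material for region(s) {names}")
    return np.array([D_by_code[c] for c in mesh.region])


def _solve_increment(nodes, mesh, D, eps_g_voigt, fixed_dofs):
    B, vol = _element_b_matrices(nodes, mesh.tets)
    Ke = np.einsum("e,eji,ejk,ekl->eil", vol, B, D, B, optimize=True)
    fe = np.einsum("e,eji,ejk,ek->ei", vol, B, D, eps_g_voigt, optimize=True)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    ndof = 3 * len(nodes)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    f = np.zeros(ndof)
    np.add.at(f, dofs.ravel(), fe.ravel())
    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(ndof)
    Kff = K[free][:, free]
    u[free] = spla.spsolve(Kff.tocsc(), f[free])
    strain = np.einsum("eij,ej->ei", B, u[dofs])
    stress = np.einsum("eij,ej->ei", D, strain - eps_g_voigt)
    return u.reshape(-1, 3), stress


def grow(
    mesh: VolumeMesh,
    field: ElementGrowthField,
    dt: float,
    n_increments: int = 12,
    materials: dict[str, Material] | None = None,
    bcs: list[BC] | None = None,
) -> GrowthStepResult:
    """Grow the mesh by the element growth field over Δt hours.

    Incremental scheme with geometry update: a spatially uniform field on a
    free body compounds to the analytic per-axis stretch (1 + g Δt/n)ⁿ and
    is stress-free; incompatible (heterogeneous or misoriented) fields
    develop residual stresses. Fails with diagnostics on element inversion
    or an under-constrained system.
    """
    if dt <= 0 or n_increments < 1:
        raise ValueError("need dt > 0 and at least one increment")
    if len(field.rates) != len(mesh.tets):
        raise ValueError("field must supply one rate triple per element")
    materials = materials or default_materials()
    bcs = bcs if bcs is not None else default_joint_bcs(mesh)
    fixed = []
    for bc in bcs:
        for ax in range(3):
            if bc.fixed[ax]:
                fixed.extend((3 * bc.nodes + ax).tolist())
    fixed_dofs = np.unique(np.array(fixed, dtype=int))
    if len(fixed_dofs) < 6:
        raise ValueError("boundary conditions leave rigid-body modes")

    D = _region_stiffness(mesh, materials)
    eps_rate = field.eigenstrain_tensors()
    eps_g = _tensor_to_voigt_strain(eps_rate) * (dt / n_increments)

    nodes = mesh.nodes.copy()
    total_u = np.zeros_like(nodes)
    stress = np.zeros((len(mesh.tets), 6))
    for inc in range(n_increments):
        try:
            u, stress = _solve_increment(nodes, mesh, D, eps_g, fixed_dofs)
        except FloatingPointError:
            return GrowthStepResult(
                nodes, total_u, stress, converged=False,
                message=f"element inversion at increment {inc}", increments=inc,
            )
        if not np.isfinite(u).all():
            return GrowthStepResult(
                nodes, total_u, stress, converged=False,
                message=f"singular system at increment {inc} "
                        "(insufficient boundary conditions?)",
                increments=inc,
            )
        nodes = nodes + u
        total_u += u
    grown = VolumeMesh(nodes, mesh.tets, mesh.region, mesh.voxel_size)
    if (grown.volumes() <= 0).any():
        return GrowthStepResult(
            nodes, total_u, stress, converged=False,
            message="negative jacobian in final mesh", increments=n_increments,
        )
    return GrowthStepResult(
        nodes, total_u, stress, converged=True, increments=n_increments
    )


def grown_mesh(mesh: VolumeMesh, result: GrowthStepResult) -> VolumeMesh:
    return VolumeMesh(result.nodes.copy(), mesh.tets.copy(), mesh.region.copy(),
                      mesh.voxel_size)


# ---------------------------------------------------------------------------
# field mapping


JOINT_REGIONS = ("MC", "PQ", "interzone")


def map_field(
    gmap: GrowthMap,
    mesh: VolumeMesh,
    zero_regions: tuple[str, ...] = ("ceratohyal",),
) -> ElementGrowthField:
    """Interpolate a growth map onto the elements of a simulation mesh.

    Strain rates (the three ellipsoid radii, as three scalar fields) are
    interpolated linearly between ROI centres via barycentric interpolation
    on the Delaunay triangulation of the valid ROI centres; elements outside
    the convex hull take the nearest valid ROI's rates. Growth directions
    are not interpolated: every element takes the axes of the ROI containing
    it (nearest valid ROI when its own is invalid), so frames are piecewise
    constant per ROI. Regions named in ``zero_regions`` and the hypertrophic
    bands (filled later by :func:`extend_hypertrophic`) are set to zero
    rates / identity frames.
    """
    idxs = gmap.valid_indices
    if not idxs:
        raise ValueError("growth map has no valid ROI")
    centres = gmap.roi_centres()
    radii = np.array([gmap.entries[i].ellipsoid.radii for i in idxs])
    axes = np.array([gmap.entries[i].ellipsoid.axes for i in idxs])

    elem_c = mesh.centroids()
    n = len(mesh.tets)
    rates = np.zeros((n, 3))
    frames = np.tile(np.eye(3), (n, 1, 1))

    target = mesh.region_mask(*JOINT_REGIONS)
    hyper = mesh.region_mask("MC_hypertrophic", "PQ_hypertrophic")
    covered = target | hyper | mesh.region_mask(*zero_regions)
    if not covered.all():
        missing = sorted({REGIONS[r] for r in np.unique(mesh.region[~covered])})
        raise ValueError(f"elements of region(s) {missing} have no growth source")

    pts = elem_c[target]
    if len(pts):
        nearest = NearestNDInterpolator(centres, radii)
        vals = None
        if len(centres) >= 5:
            try:
                lin = LinearNDInterpolator(centres, radii)
                vals = lin(pts)
            except QhullError:
                vals = None
        if vals is None:
            vals = np.full((len(pts), 3), np.nan)
        bad = ~np.isfinite(vals).all(axis=1)
        if bad.any():
            vals[bad] = nearest(pts[bad])
        rates[target] = vals
        tree = cKDTree(centres)
        _, which = tree.query(pts)
        frames[target] = axes[which]
    return ElementGrowthField(rates=rates, frames=frames)


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


@dataclass
class OrientationRegression:
    """Linear trend of cell orientation with distance from the joint line.

    angle(d) = slope · d + intercept (degrees, d in μm), applied as a
    rotation about the mediolateral axis to the MC hypertrophic frames; the
    coefficients are measured inputs, zero by default (no rotation).
    """

    slope_deg_per_um: float = 0.0
    intercept_deg: float = 0.0
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)


def extend_hypertrophic(
    fld: ElementGrowthField,
    mesh: VolumeMesh,
    joint_line_z: float,
    depth: float = 30.0,
    regression: OrientationRegression | None = None,
) -> ElementGrowthField:
    """Fill hypertrophic regions from the adjacent proliferative cartilage.

    Each hypertrophic band inherits the growth of the 30-μm-deep
    (configurable) band of adjacent proliferative cartilage of the same
    rudiment: the band's eigenstrain-rate tensors are averaged and the mean
    tensor's ellipsoid supplies both the rates and the single material
    orientation used throughout the region (averaging the tensor rather
    than per-element frames keeps eigenvector noise from leaking the main
    rate into spurious bending of the long hypertrophic shaft). In the MC
    hypertrophic region — where cell orientation varies along the rudiment —
    that orientation is additionally rotated by the linear orientation
    regression evaluated at each element's distance from the joint line.
    """
    regression = regression or OrientationRegression()
    rates = fld.rates.copy()
    frames = fld.frames.copy()
    eps = fld.eigenstrain_tensors()
    cent = mesh.centroids()
    for rud, hyper_name in (("MC", "MC_hypertrophic"), ("PQ", "PQ_hypertrophic")):
        hyper = mesh.region_mask(hyper_name)
        if not hyper.any():
            continue
        prolif = mesh.region_mask(rud)
        if not prolif.any():
            raise ValueError(f"no proliferative {rud} cartilage adjacent to "
                             f"{hyper_name}")
        tree = cKDTree(cent[hyper])
        d_to_hyper, _ = tree.query(cent[prolif])
        pad = (mesh.voxel_size or 0.0) * 0.5
        band = d_to_hyper <= depth + pad
        if not band.any():
            raise ValueError(f"empty proliferative band next to {hyper_name}")
        band_idx = np.where(prolif)[0][band]
        mean_tensor = eps[band_idx].mean(axis=0)
        w, vecs = np.linalg.eigh(0.5 * (mean_tensor + mean_tensor.T))
        order = np.argsort(-np.abs(w), kind="stable")
        band_rates = w[order]
        band_frame = vecs[:, order]
        if np.linalg.det(band_frame) < 0:
            band_frame[:, 2] = -band_frame[:, 2]
        rates[hyper] = band_rates
        if rud == "PQ":
            frames[hyper] = band_frame
        else:
            d = np.abs(cent[hyper][:, 2] - joint_line_z)
            ang = np.deg2rad(
                regression.slope_deg_per_um * d + regression.intercept_deg
            )
            hyper_ids = np.where(hyper)[0]
            for i, a in zip(hyper_ids, ang):
                frames[i] = _rotation_about(regression.rotation_axis, a) @ band_frame
    return ElementGrowthField(rates=rates, frames=frames)


def extend_to_region(
    fld: ElementGrowthField,
    mesh: VolumeMesh,
    region: str,
    source_regions: tuple[str, ...],
) -> ElementGrowthField:
    """Copy growth from the nearest source element into another region.

    Used for the ceratohyal: it carries the boundary conditions rather than
    a measured growth field, but a rigidly non-growing anchor would bend the
    growing jaw against it, so it inherits the growth of the adjacent
    posterior cartilage element-by-element.
    """
    target = mesh.region_mask(region)
    if not target.any():
        return fld
    source = mesh.region_mask(*source_regions)
    if not source.any():
        raise ValueError(f"no source elements for region {region!r}")
    cent = mesh.centroids()
    src_idx = np.where(source)[0]
    _, nearest = cKDTree(cent[src_idx]).query(cent[target])
    rates = fld.rates.copy()
    frames = fld.frames.copy()
    rates[target] = fld.rates[src_idx][nearest]
    frames[target] = fld.frames[src_idx][nearest]
    return ElementGrowthField(rates=rates, frames=frames)


# ---------------------------------------------------------------------------
# ablation transforms


def homogenize(gmap: GrowthMap, masks: dict[str, object]) -> GrowthMap:
    """Remove spatial growth heterogeneity within each rudiment.

    ``masks`` maps a rudiment label to a predicate on ROI centres; within
    each rudiment's set of ROIs the tensors are averaged and the mean
    ellipsoid is assigned back to every member ROI, so the rudiment-mean
    tensor is conserved exactly. Growth directions then no longer vary from
    ROI to ROI, only between rudiments.
    """
    out = GrowthMap(grid=gmap.grid, window=gmap.window)
    assigned = set()
    for _, pred in masks.items():
        members = [
            i for i in gmap.valid_indices if pred(gmap.grid.centre(i))
            and i not in assigned
        ]
        if not members:
            continue
        assigned.update(members)
        mean_tensor = np.mean([gmap.entries[i].tensor for i in members], axis=0)
        ell = decompose(mean_tensor)
        for i in members:
            e = gmap.entries[i]
            out.entries[i] = ROIEntry(
                tensor=mean_tensor.copy(), ellipsoid=ell,
                n_links=e.n_links, n_samples=e.n_samples,
            )
    for i in gmap.valid_indices:
        if i not in assigned:
            out.entries[i] = gmap.entries[i]
    return out


def isotropize(gmap: GrowthMap) -> GrowthMap:
    """Remove growth orientation: each ROI ellipsoid becomes a sphere.

    The sphere radius is the mean of the three ellipsoid radii, so the
    tensor trace (volumetric rate) is preserved exactly per ROI while all
    directional information is discarded.
    """
    out = GrowthMap(grid=gmap.grid, window=gmap.window)
    for i, e in gmap.entries.items():
        r = float(np.mean(e.ellipsoid.radii))
        V = np.eye(3) * r
        out.entries[i] = ROIEntry(
            tensor=V, ellipsoid=decompose(V),
            n_links=e.n_links, n_samples=e.n_samples,
        )
    return out
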