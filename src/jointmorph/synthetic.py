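"""Synthetic cell clouds, track maps and toy joint meshes with known growth.

Every downstream stage of the pipeline (link building, velocity-gradient
estimation, finite-element growth, scoring) is validated against data
generated here, because the imposed velocity-gradient tensor L is known
exactly: with the default linearised update the recoverable ground truth is
sym(L) by construction.

Conventions (package-wide): x = medial→lateral, y = ventral→dorsal,
z = anterior→posterior; lengths in μm, time in hours, rates in h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .meshing import REGION_CODE, VolumeMesh, tet_mesh_from_regions

CELL_COLUMNS = [
    "sample_id",
    "timepoint_h",
    "cell_id",
    "x_um",
    "y_um",
    "z_um",
    "rudiment",
    "col2_positive",
    "volume_um3",
]


@dataclass(frozen=True)
class RodGeometry:
    """Rod-shaped rudiment descriptor.

    The rod runs along the anteroposterior (z) axis from ``z0`` to ``z1``
    with a cross-section of semi-axes ``rx`` (mediolateral) and ``ry``
    (ventrodorsal) centred at ``(cx, cy)``; the section is elliptic by
    default or rectangular with ``section="box"``. All lengths in μm.
    """

    cx: float = 0.0
    cy: float = 0.0
    rx: float = 12.0
    ry: float = 10.0
    z0: float = 0.0
    z1: float = 60.0
    section: str = "ellipse"

    @property
    def volume(self) -> float:
        area = (
            np.pi * self.rx * self.ry
            if self.section == "ellipse"
            else 4.0 * self.rx * self.ry
        )
        return float(area * (self.z1 - self.z0))

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.cx, self.cy, 0.5 * (self.z0 + self.z1)])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self.section == "ellipse":
            in_section = (
                ((pts[:, 0] - self.cx) / self.rx) ** 2
                + ((pts[:, 1] - self.cy) / self.ry) ** 2
                <= 1.0
            )
        else:
            in_section = (np.abs(pts[:, 0] - self.cx) <= self.rx) & (
                np.abs(pts[:, 1] - self.cy) <= self.ry
            )
        return in_section & (pts[:, 2] >= self.z0) & (pts[:, 2] <= self.z1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample n points uniformly inside the rod."""
        out = np.empty((0, 3))
        while len(out) < n:
            m = max(4 * (n - len(out)), 16)
            cand = rng.uniform(
                [self.cx - self.rx, self.cy - self.ry, self.z0],
                [self.cx + self.rx, self.cy + self.ry, self.z1],
                size=(m, 3),
            )
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]


@dataclass
class SyntheticSpec:
    """Recipe for one rudiment's synthetic cell cloud over one window.

    ``imposed_field`` is the velocity-gradient tensor L (h⁻¹) driving the
    cloud between ``window[0]`` and ``window[1]`` (hours). ``division_rate``
    is the fraction of cells dividing over the whole window, matching the
    rare divisions seen in larval jaw joints (≈0–2.5 % per 12 h).
    """

    n_cells: int = 50
    geometry: RodGeometry = field(default_factory=RodGeometry)
    window: tuple[float, float] = (84.0, 96.0)
    imposed_field: np.ndarray = field(
        default_factory=lambda: np.diag([0.001, 0.004, 0.02])
    )
    centroid_noise_sd: float = 0.2
    division_rate: float = 0.0
    min_spacing: float = 6.0
    volume_expansion: float = 0.1849
    seed: int = 0
    rudiment: str = "MC"
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.imposed_field = np.asarray(self.imposed_field, dtype=float)
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells per rudiment")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must satisfy t1 > t0")
        if self.centroid_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0 <= self.division_rate <= 1:
            raise ValueError("division_rate must lie in [0, 1]")
        if self.imposed_field.shape != (3, 3) or not np.isfinite(
            self.imposed_field
        ).all():
            raise ValueError("imposed_field must be a finite 3x3 tensor")
        if self.geometry.volume <= 0:
            raise ValueError("degenerate rudiment geometry (zero volume)")


@dataclass
class SyntheticGroundTruth:
    """Exact recoverable quantities for one synthetic window."""

    rate_tensor: np.ndarray  # sym(L), h⁻¹
    centre: np.ndarray  # fixed point of the imposed flow, μm
    window: tuple[float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "rate_tensor": self.rate_tensor.tolist(),
            "centre": self.centre.tolist(),
            "window": list(self.window),
            "seed": self.seed,
        }


def _cells_frame(spec, pts, ids, t, volumes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": spec.sample_id,
            "timepoint_h": t,
            "cell_id": ids,
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
            "rudiment": spec.rudiment,
            "col2_positive": True,
            "volume_um3": volumes,
        },
        columns=CELL_COLUMNS,
    )


def generate_rudiment_cells(spec: SyntheticSpec) -> pd.DataFrame:
    """Seed a rudiment with cell centroids at the window start.

    Centroids are placed uniformly inside the rod with a hard-core minimum
    spacing (``spec.min_spacing``) enforced by dart throwing, mimicking the
    packing of chondrocytes; per-cell volumes are drawn around the volume of
    a sphere of half the spacing. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * spec.n_cells
    while len(pts) < spec.n_cells:
        cand = spec.geometry.sample(1, rng)[0]
        if not pts or (
            np.linalg.norm(np.array(pts) - cand, axis=1).min() >= spec.min_spacing
        ):
            pts.append(cand)
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place cells at the requested hard-core spacing; "
                "reduce min_spacing or n_cells"
            )
    pts = np.array(pts)
    r = spec.min_spacing / 2.0
    volumes = 4.0 / 3.0 * np.pi * r**3 * rng.uniform(0.8, 1.2, size=spec.n_cells)
    ids = [f"{spec.rudiment}_{i:04d}" for i in range(spec.n_cells)]
    return _cells_frame(spec, pts, ids, spec.window[0], volumes)


def apply_growth_field(
    cells_t0: pd.DataFrame,
    spec: SyntheticSpec,
    centre: np.ndarray | None = None,
    exact_exponential: bool = False,
):
    """Advect a cell cloud through the imposed velocity-gradient flow.

    Each centroid p is moved to ``p + L (p − c) Δt`` about the stated fixed
    point c (the rudiment centre by default), then perturbed by i.i.d.
    Gaussian centroid noise. With ``exact_exponential=True`` the deformation
    gradient ``expm(L Δt)`` is used instead of the linearised update; the
    default linearisation makes the ground-truth rate tensor exactly sym(L)
    in the small-rate regime of larval cartilage (|L| Δt ≲ 0.3).

    Divisions: a ``division_rate`` fraction of cells (binomial draw) each
    produce one daughter that keeps the parent id and one with a fresh id at
    a small offset, mirroring how tracked divisions enter real track maps.
    Cell volumes grow by ``volume_expansion`` on average.

    Returns
    -------
    (cells_t1, track, truth) : (DataFrame, DataFrame, SyntheticGroundTruth)
        ``track`` has columns ``cell_id_t0, cell_id_t1, event`` with event
        in {tracked, divided}.
    """
    L = np.asarray(spec.imposed_field, dtype=float)
    t0, t1 = spec.window
    dt = t1 - t0
    if dt <= 0:
        raise ValueError("window duration must be positive")
    if not np.isfinite(L).all():
        raise ValueError("imposed field must be finite")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    p0 = cells_t0[["x_um", "y_um", "z_um"]].to_numpy()
    if centre is None:
        centre = spec.geometry.centre
    centre = np.asarray(centre, dtype=float)

    if exact_exponential:
        F = expm(L * dt)
        p1 = centre + (p0 - centre) @ F.T
    else:
        p1 = p0 + (p0 - centre) @ (L.T * dt)
    if spec.centroid_noise_sd > 0:
        p1 = p1 + rng.normal(0.0, spec.centroid_noise_sd, size=p1.shape)

    ids0 = cells_t0["cell_id"].tolist()
    vol0 = cells_t0["volume_um3"].to_numpy()
    growth = np.clip(
        rng.normal(spec.volume_expansion, 0.25 * abs(spec.volume_expansion) + 1e-12,
                   size=len(vol0)),
        -0.5,
        None,
    )
    vol1 = vol0 * (1.0 + growth)

    n_div = rng.binomial(len(ids0), spec.division_rate)
    dividing = set(rng.choice(len(ids0), size=n_div, replace=False).tolist())

    rows_t1 = []
    track_rows = []
    next_id = len(ids0)
    for i, cid in enumerate(ids0):
        rows_t1.append((cid, p1[i], vol1[i] if i not in dividing else vol1[i] / 2))
        if i in dividing:
            new_id = f"{spec.rudiment}_{next_id:04d}"
            next_id += 1
            offset = rng.normal(0.0, 1.0, size=3)
            offset *= spec.min_spacing / 2 / max(np.linalg.norm(offset), 1e-9)
            rows_t1.append((new_id, p1[i] + offset, vol1[i] / 2))
            track_rows.append((cid, cid, "divided"))
            track_rows.append((cid, new_id, "divided"))
        else:
            track_rows.append((cid, cid, "tracked"))

    ids1 = [r[0] for r in rows_t1]
    pts1 = np.array([r[1] for r in rows_t1])
    vols1 = np.array([r[2] for r in rows_t1])
    cells_t1 = _cells_frame(spec, pts1, ids1, t1, vols1)
    track = pd.DataFrame(track_rows, columns=["cell_id_t0", "cell_id_t1", "event"])
    truth = SyntheticGroundTruth(
        rate_tensor=0.5 * (L + L.T), centre=centre, window=spec.window, seed=spec.seed
    )
    return cells_t1, track, truth


# ---------------------------------------------------------------------------
# Toy joint mesh


@dataclass
class ToyJointParams:
    """Parametric half-jaw joint used as the simulation domain.

    Meckel's cartilage (MC) lies anterior (low z), the palatoquadrate (PQ)
    posterior (high z), separated by an interzone gap that the interzone
    region fills (cross-section of the larger, posterior element).
    Hypertrophic bands are the rudiment portions further than
    ``hypertrophic_offset`` μm from the joint line; the ceratohyal is a
    ventral bar attached under the PQ, present only to carry physiological
    boundary conditions.

    The default rods use rectangular sections whose faces lie on lattice
    planes of the default voxel sizes, so the voxelised mesh reproduces the
    parametric volume exactly at every refinement level.
    """

    mc: RodGeometry = field(
        default_factory=lambda: RodGeometry(0, 0, 10, 10, 0, 70, section="box")
    )
    pq: RodGeometry = field(
        default_factory=lambda: RodGeometry(0, 0, 15, 10, 80, 160, section="box")
    )
    interzone_z: tuple[float, float] = (70.0, 80.0)
    hypertrophic_offset: float = 30.0
    ceratohyal: tuple[float, float, float, float, float, float] = (
        -10.0, 10.0, -20.0, -10.0, 100.0, 160.0,
    )  # x0, x1, y0, y1, z0, z1
    voxel_size: float = 5.0

    def joint_line_z(self) -> float:
        return 0.5 * (self.interzone_z[0] + self.interzone_z[1])


def generate_toy_joint_mesh(params: ToyJointParams | None = None) -> VolumeMesh:
    """Build the labelled toy joint tet mesh.

    The MC/PQ rods must leave a strictly positive interzone gap and the
    ceratohyal bar must not overlap either rudiment; overlapping region
    specifications are rejected. Elements are labelled MC / PQ /
    MC_hypertrophic / PQ_hypertrophic / interzone / ceratohyal.
    """
    p = params or ToyJointParams()
    if not (p.mc.z1 <= p.interzone_z[0] < p.interzone_z[1] <= p.pq.z0):
        raise ValueError("interzone must fill a positive gap between MC and PQ")
    cx0, cx1, cy0, cy1, cz0, cz1 = p.ceratohyal
    # overlap check: ceratohyal box corners (shrunk marginally towards its
    # centre, so a shared face does not count as overlap) against rudiments
    centre = np.array([(cx0 + cx1) / 2, (cy0 + cy1) / 2, (cz0 + cz1) / 2])
    corners = np.array(
        [(x, y, z) for x in (cx0, cx1) for y in (cy0, cy1) for z in (cz0, cz1)]
    )
    probe = np.vstack([centre + (corners - centre) * (1 - 1e-9), centre[None]])
    if p.mc.contains(probe).any() or p.pq.contains(probe).any():
        raise ValueError("ceratohyal overlaps a rudiment")

    iz_lo, iz_hi = p.interzone_z
    hyp = p.hypertrophic_offset

    def region_of(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        code = np.full(len(pts), -1, dtype=int)
        z = pts[:, 2]
        in_mc = p.mc.contains(pts)
        in_pq = p.pq.contains(pts)
        code[in_mc] = REGION_CODE["MC"]
        code[in_mc & (z < p.mc.z1 - hyp)] = REGION_CODE["MC_hypertrophic"]
        code[in_pq] = REGION_CODE["PQ"]
        code[in_pq & (z > p.pq.z0 + hyp)] = REGION_CODE["PQ_hypertrophic"]
        # interzone: gap filled with the posterior element's cross-section
        iz_section = RodGeometry(
            p.pq.cx, p.pq.cy, p.pq.rx, p.pq.ry, iz_lo, iz_hi, section=p.pq.section
        )
        in_iz = (z >= iz_lo) & (z < iz_hi) & iz_section.contains(pts)
        code[in_iz] = REGION_CODE["interzone"]
        in_ch = (
            (pts[:, 0] >= cx0) & (pts[:, 0] <= cx1)
            & (pts[:, 1] >= cy0) & (pts[:, 1] <= cy1)
            & (z >= cz0) & (z <= cz1)
        )
        if (in_ch & (code >= 0)).any():
            raise ValueError("overlapping regions in toy joint specification")
        code[in_ch] = REGION_CODE["ceratohyal"]
        return code

    lo = [
        min(p.mc.cx - p.mc.rx, p.pq.cx - p.pq.rx, cx0),
        min(p.mc.cy - p.mc.ry, p.pq.cy - p.pq.ry, cy0),
        min(p.mc.z0, cz0),
    ]
    hi = [
        max(p.mc.cx + p.mc.rx, p.pq.cx + p.pq.rx, cx1),
        max(p.mc.cy + p.mc.ry, p.pq.cy + p.pq.ry, cy1),
        max(p.pq.z1, cz1),
    ]
    return tet_mesh_from_regions(region_of, [lo, hi], voxel_size=p.voxel_size)


def joint_element_specs(
    params: ToyJointParams,
    window: tuple[float, float],
    fields: dict[str, np.ndarray],
    n_cells: dict[str, int] | int = 40,
    noise_sd: float = 0.2,
    division_rates: dict[str, float] | None = None,
    volume_expansions: dict[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> dict[str, SyntheticSpec]:
    """Specs for the two tracked joint elements of the toy jaw.

    The tracked cell populations occupy the proliferative (non-hypertrophic)
    portions of MC and PQ adjacent to the joint line, which is where live
    imaging resolves cells.
    """
    division_rates = division_rates or {"MC": 0.0242, "PQ": 0.005}
    volume_expansions = volume_expansions or {"MC": 0.1849, "PQ": 0.2368}
    if isinstance(n_cells, int):
        n_cells = {"MC": n_cells, "PQ": n_cells}
    hyp = params.hypertrophic_offset
    geoms = {
        "MC": RodGeometry(
            params.mc.cx, params.mc.cy, params.mc.rx, params.mc.ry,
            params.mc.z1 - hyp, params.mc.z1, section=params.mc.section,
        ),
        "PQ": RodGeometry(
            params.pq.cx, params.pq.cy, params.pq.rx, params.pq.ry,
            params.pq.z0, params.pq.z0 + hyp, section=params.pq.section,
        ),
    }
    out = {}
    for i, rud in enumerate(("MC", "PQ")):
        out[rud] = SyntheticSpec(
            n_cells=n_cells[rud],
            geometry=geoms[rud],
            window=window,
            imposed_field=np.asarray(fields[rud], dtype=float),
            centroid_noise_sd=noise_sd,
            division_rate=division_rates[rud],
            volume_expansion=volume_expansions[rud],
            seed=int(np.random.SeedSequence([seed, 7 + i]).generate_state(1)[0] % (2**31)),
            rudiment=rud,
            sample_id=sample_id,
        )
    return out
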