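"""Per-ROI statistical velocity gradients and growth maps.

A cubic grid (side 15 μm by default) is superimposed on the aligned joint.
In each region of interest (ROI) the local tissue deformation rate is
estimated from the conserved centroid-to-centroid links with the texture
method for discrete rearranging patterns: with M = ⟨ℓ₀ ⊗ ℓ₀⟩ the texture
tensor and C = ⟨ℓ₀ ⊗ Δℓ⟩ / Δt the link-change tensor, the statistical
velocity gradient is

    V = sym(M⁻¹ C),

which for links carried by a uniform affine velocity gradient L recovers
sym(L) exactly. V is represented as a growth ellipsoid: its eigenvalues,
ordered by descending magnitude (main / second / third direction), are the
local strain rates (h⁻¹) and its eigenvectors the growth directions. Maps
from several specimens are averaged per ROI after discarding outlier
samples by an interquartile-range rule on the main radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .links import ConservedLinkSet


@dataclass(frozen=True)
class ROIGrid:
    """Cubic ROI grid: half-open cells ``[origin + i*side, origin + (i+1)*side)``."""

    origin: tuple[float, float, float]
    side: float = 15.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("grid side must be positive")

    @classmethod
    def covering(cls, points: np.ndarray, side: float = 15.0, pad: float = 1e-6):
        """Smallest grid of the given side covering a point cloud."""
        pts = np.asarray(points, dtype=float)
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        dims = np.maximum(np.ceil((hi - lo) / side).astype(int), 1)
        return cls(origin=tuple(lo), side=float(side), dims=tuple(int(d) for d in dims))

    def index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.floor((pts - np.asarray(self.origin)) / self.side).astype(int)

    def centre(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(idx) + 0.5) * self.side

    def contains_index(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool((idx >= 0).all() and (idx < np.asarray(self.dims)).all())


@dataclass
class GrowthTensor:
    """Symmetric statistical velocity gradient for one ROI (h⁻¹)."""

    V: np.ndarray
    roi_index: tuple[int, int, int]
    n_links: int
    valid: bool = True


@dataclass
class GrowthEllipsoid:
    """Eigen-representation of a growth tensor.

    ``radii`` are the eigenvalues sorted by descending |λ| (main, second,
    third direction); ``axes`` columns are the matching orthonormal
    eigenvectors with a deterministic sign (largest-magnitude component of
    each axis is positive).
    """

    radii: np.ndarray
    axes: np.ndarray

    @property
    def main_radius(self) -> float:
        return float(self.radii[0])

    def tensor(self) -> np.ndarray:
        return self.axes @ np.diag(self.radii) @ self.axes.T


def roi_velocity_gradient(
    l0: np.ndarray,
    l1: np.ndarray,
    dt: float,
    roi_index=(0, 0, 0),
    min_links: int = 4,
    cond_max: float = 1e8,
) -> GrowthTensor:
    """Estimate V = sym(M⁻¹C) from one ROI's conserved links.

    Marked invalid (never zero-filled) when fewer than ``min_links`` links
    are available or the texture tensor M is ill-conditioned: a rank-
    deficient link set cannot constrain a 3D rate tensor.
    """
    l0 = np.asarray(l0, dtype=float)
    l1 = np.asarray(l1, dtype=float)
    n = len(l0)
    if n < min_links:
        return GrowthTensor(np.full((3, 3), np.nan), tuple(roi_index), n, valid=False)
    M = l0.T @ l0 / n
    C = l0.T @ (l1 - l0) / (n * dt)
    if np.linalg.cond(M) > cond_max:
        return GrowthTensor(np.full((3, 3), np.nan), tuple(roi_index), n, valid=False)
    G = np.linalg.solve(M, C)
    V = 0.5 * (G + G.T)
    return GrowthTensor(V, tuple(roi_index), n, valid=True)


def decompose(tensor: GrowthTensor | np.ndarray) -> GrowthEllipsoid:
    """Eigen-decompose a symmetric rate tensor into a growth ellipsoid.

    Eigenvalues are reordered by descending absolute value so that the main
    direction is the one with the largest strain-rate magnitude regardless
    of sign (a strong contraction outranks a mild expansion).
    """
    V = tensor.V if isinstance(tensor, GrowthTensor) else np.asarray(tensor, float)
    V = 0.5 * (V + V.T)
    w, vecs = np.linalg.eigh(V)
    order = np.argsort(-np.abs(w), kind="stable")
    w = w[order]
    vecs = vecs[:, order]
    for j in range(3):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return GrowthEllipsoid(radii=w, axes=vecs)


@dataclass
class ROIEntry:
    tensor: np.ndarray
    ellipsoid: GrowthEllipsoid
    n_links: int
    n_samples: int = 1


@dataclass
class GrowthMap:
    """Per-ROI growth ellipsoids over one time window."""

    grid: ROIGrid
    window: tuple[float, float]
    entries: dict[tuple[int, int, int], ROIEntry] = field(default_factory=dict)

    @property
    def valid_indices(self) -> list[tuple[int, int, int]]:
        return sorted(self.entries)

    def roi_centres(self) -> np.ndarray:
        return np.array([self.grid.centre(i) for i in self.valid_indices])

    # serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid": {
                "origin": list(self.grid.origin),
                "side": self.grid.side,
                "dims": list(self.grid.dims),
            },
            "window": list(self.window),
            "rois": [
                {
                    "index": [int(i) for i in idx],
                    "tensor": e.tensor.tolist(),
                    "radii": e.ellipsoid.radii.tolist(),
                    "axes": e.ellipsoid.axes.tolist(),
                    "n_links": int(e.n_links),
                    "n_samples": int(e.n_samples),
                }
                for idx, e in sorted(self.entries.items())
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthMap":
        grid = ROIGrid(
            origin=tuple(d["grid"]["origin"]),
            side=d["grid"]["side"],
            dims=tuple(d["grid"]["dims"]),
        )
        entries = {}
        for r in d["rois"]:
            entries[tuple(r["index"])] = ROIEntry(
                tensor=np.array(r["tensor"]),
                ellipsoid=GrowthEllipsoid(
                    radii=np.array(r["radii"]), axes=np.array(r["axes"])
                ),
                n_links=r["n_links"],
                n_samples=r["n_samples"],
            )
        return cls(grid=grid, window=tuple(d["window"]), entries=entries)

    @classmethod
    def load(cls, path) -> "GrowthMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def assign_links_to_rois(
    conserved: ConservedLinkSet, grid: ROIGrid
) -> dict[tuple[int, int, int], np.ndarray]:
    """Assign each conserved link to every ROI containing one of its t0 endpoints.

    A link spanning two ROIs contributes to both; the return maps ROI index
    to the integer row indices of the links assigned to it.
    """
    a, b = conserved.endpoints_t0
    ia = grid.index(a)
    ib = grid.index(b)
    out: dict[tuple[int, int, int], list[int]] = {}
    for row in range(len(conserved)):
        rois = {tuple(int(v) for v in ia[row])}
        rois.add(tuple(int(v) for v in ib[row]))
        for idx in rois:
            out.setdefault(idx, []).append(row)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def compute_growth_map(
    conserved: ConservedLinkSet,
    grid: ROIGrid | None = None,
    window: tuple[float, float] = (0.0, 12.0),
    side: float = 15.0,
    min_links: int = 4,
) -> GrowthMap:
    """Full per-ROI velocity-gradient map for one specimen and window."""
    if grid is None:
        a, b = conserved.endpoints_t0
        grid = ROIGrid.covering(np.vstack([a, b]), side=side)
    per_roi = assign_links_to_rois(conserved, grid)
    l0, l1 = conserved.l0, conserved.l1
    entries = {}
    for idx, rows in per_roi.items():
        t = roi_velocity_gradient(
            l0[rows], l1[rows], conserved.dt, roi_index=idx, min_links=min_links
        )
        if t.valid:
            entries[idx] = ROIEntry(
                tensor=t.V, ellipsoid=decompose(t), n_links=t.n_links
            )
    return GrowthMap(grid=grid, window=window, entries=entries)


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    # linear-interpolation quartiles (inclusive of the median), numpy default
    return tuple(np.percentile(x, [25, 75], method="linear"))


def outlier_mask(main_radii: np.ndarray, rule: str = "tukey") -> np.ndarray:
    """True for samples to KEEP under the configured interquartile rule.

    "tukey": keep values within [Q1 − 1.5·IQR, Q3 + 1.5·IQR];
    "strict": keep only values within [Q1, Q3].

    With two or fewer samples no rule can identify an outlier, so nothing
    is removed.
    """
    x = np.asarray(main_radii, dtype=float)
    if len(x) <= 2:
        return np.ones(len(x), dtype=bool)
    q1, q3 = _quartiles(x)
    if rule == "tukey":
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    elif rule == "strict":
        lo, hi = q1, q3
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    return (x >= lo) & (x <= hi)


def average_maps(maps: list[GrowthMap], outlier_rule: str = "tukey") -> GrowthMap:
    """Average specimen growth maps per ROI with outlier-sample removal.

    For each ROI the per-sample main radii are screened by the chosen
    interquartile rule; the surviving samples' full tensors are averaged
    component-wise and the mean tensor re-decomposed. Subject-specific maps
    often contain noticeably higher or lower local rates, which averaging
    with outlier removal suppresses before the rates drive a simulation.
    """
    if not maps:
        raise ValueError("need at least one map to average")
    g0 = maps[0].grid
    for m in maps[1:]:
        if (m.grid.side != g0.side or tuple(m.grid.origin) != tuple(g0.origin)):
            raise ValueError("maps must share a common ROI grid")
    all_indices = sorted({idx for m in maps for idx in m.entries})
    out = GrowthMap(grid=g0, window=maps[0].window)
    for idx in all_indices:
        tensors, mains, nlinks = [], [], []
        for m in maps:
            e = m.entries.get(idx)
            if e is not None:
                tensors.append(e.tensor)
                mains.append(e.ellipsoid.main_radius)
                nlinks.append(e.n_links)
        if not tensors:
            continue
        keep = outlier_mask(np.array(mains), rule=outlier_rule)
        if not keep.any():
            continue
        kept = [t for t, k in zip(tensors, keep) if k]
        mean_tensor = np.mean(kept, axis=0)
        out.entries[idx] = ROIEntry(
            tensor=mean_tensor,
            ellipsoid=decompose(mean_tensor),
            n_links=int(np.sum([n for n, k in zip(nlinks, keep) if k])),
            n_samples=int(keep.sum()),
        )
    return out


def summarize_rates(
    gmap: GrowthMap, roi_filter=None, label: str = "all"
) -> pd.DataFrame:
    """Mean ± sd strain rate per growth direction over the selected ROIs.

    ``roi_filter`` is an optional predicate on the ROI centre coordinates
    (μm) selecting e.g. one rudiment's ROIs. Returns a tidy frame with one
    row per direction (main / second / third); rates in h⁻¹.
    """
    radii = []
    for idx, e in gmap.entries.items():
        c = gmap.grid.centre(idx)
        if roi_filter is None or roi_filter(c):
            radii.append(e.ellipsoid.radii)
    if not radii:
        raise ValueError("no valid ROI matches the requested mask")
    radii = np.array(radii)
    return pd.DataFrame(
        {
            "region": label,
            "direction": ["main", "second", "third"],
            "mean_rate_per_h": radii.mean(axis=0),
            "sd_rate_per_h": radii.std(axis=0, ddof=1) if len(radii) > 1 else 0.0,
            "n_rois": len(radii),
        }
    )


def uniform_map(
    grid: ROIGrid,
    window: tuple[float, float],
    tensor_of_centre,
    n_links: int = 0,
) -> GrowthMap:
    """Growth map with an analytically prescribed tensor in every grid ROI.

    ``tensor_of_centre`` maps an ROI centre (μm) to a symmetric 3×3 rate
    tensor or ``None`` (ROI left invalid). Used to build ground-truth maps
    for synthetic experiments.
    """
    out = GrowthMap(grid=grid, window=window)
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                c = grid.centre((i, j, k))
                V = tensor_of_centre(c)
                if V is None:
                    continue
                V = 0.5 * (np.asarray(V, float) + np.asarray(V, float).T)
                out.entries[(i, j, k)] = ROIEntry(
                    tensor=V, ellipsoid=decompose(V), n_links=n_links
                )
    return out
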