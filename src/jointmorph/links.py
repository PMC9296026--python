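"""Centroid adjacency links and cell-dynamics summary metrics.

Growth quantification rests on vectors joining the centroids of adjoining
cells. Adjacency defaults to the edges of the 3D Delaunay tessellation of
the cloud, pruned at a maximum link length (1.5 × the median Delaunay edge
length unless given), which is the standard discrete-pattern construction
for texture-tensor methods; k-nearest-neighbour and fixed-radius adjacency
are available as alternatives. Links conserved across a 12-h window (both
endpoints tracked) carry the pair of vectors (ℓ_t0, ℓ_t1) consumed by the
velocity-gradient estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

LINK_COLUMNS = ["cell_a", "cell_b", "lx", "ly", "lz"]


def filter_col2(cells: pd.DataFrame) -> pd.DataFrame:
    """Drop col2-negative cells (interzone cells, not tracked)."""
    if "col2_positive" not in cells.columns:
        return cells
    return cells[cells["col2_positive"].astype(bool)].reset_index(drop=True)


def _positions(cells: pd.DataFrame):
    ids = cells["cell_id"].to_numpy()
    pts = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("non-finite centroid coordinates")
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate cell ids at one timepoint")
    return ids, pts


def _delaunay_edges(pts: np.ndarray) -> np.ndarray:
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = sorted((simplex[i], simplex[j]))
                edges.add((a, b))
    return np.array(sorted(edges), dtype=int)


def _knn_edges(pts: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(pts)
    k_eff = min(k + 1, len(pts))
    _, idx = tree.query(pts, k=k_eff)
    edges = set()
    for i, row in enumerate(np.atleast_2d(idx)):
        for j in row[1:]:
            edges.add(tuple(sorted((i, int(j)))))
    return np.array(sorted(edges), dtype=int)


def build_adjacency(
    cells: pd.DataFrame,
    method: str = "delaunay",
    max_link_length: float | None = None,
    k: int = 6,
    radius: float | None = None,
    exclude_col2_negative: bool = True,
) -> pd.DataFrame:
    """List links between adjoining cells at one timepoint.

    Parameters
    ----------
    cells : DataFrame with cell_id, x_um, y_um, z_um (one timepoint).
    method : "delaunay" (default), "knn" or "radius".
    max_link_length : prune links longer than this (μm). ``None`` uses
        1.5 × the median raw edge length for delaunay/knn; required for
        "radius".

    Returns
    -------
    DataFrame with columns cell_a, cell_b, lx, ly, lz where
    ℓ = position(b) − position(a); the adjacency is symmetric and each
    unordered pair appears once.
    """
    if exclude_col2_negative:
        cells = filter_col2(cells)
    ids, pts = _positions(cells)
    if len(ids) < 2:
        raise ValueError("need at least 2 cells to build links")

    if method == "delaunay":
        try:
            edges = _delaunay_edges(pts)
        except QhullError:
            warnings.warn(
                "degenerate (coplanar/collinear) cloud: falling back to "
                "k-nearest-neighbour adjacency",
                RuntimeWarning,
                stacklevel=2,
            )
            edges = _knn_edges(pts, k)
    elif method == "knn":
        edges = _knn_edges(pts, k)
    elif method == "radius":
        if radius is None and max_link_length is None:
            raise ValueError("radius adjacency requires a radius")
        r = radius if radius is not None else max_link_length
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r)
        edges = np.array(sorted(tuple(sorted(p)) for p in pairs), dtype=int)
    else:
        raise ValueError(f"unknown adjacency method {method!r}")

    if len(edges) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)
    vec = pts[edges[:, 1]] - pts[edges[:, 0]]
    length = np.linalg.norm(vec, axis=1)
    if (length == 0).any():
        raise ValueError("coincident centroids produce zero-length links")
    cutoff = max_link_length
    if cutoff is None and method in ("delaunay", "knn"):
        cutoff = 1.5 * float(np.median(length))
    if cutoff is not None:
        keep = length <= cutoff
        edges, vec = edges[keep], vec[keep]
    return pd.DataFrame(
        {
            "cell_a": ids[edges[:, 0]],
            "cell_b": ids[edges[:, 1]],
            "lx": vec[:, 0],
            "ly": vec[:, 1],
            "lz": vec[:, 2],
        }
    )


@dataclass
class ConservedLinkSet:
    """Link vectors conserved across one time window.

    ``frame`` columns: cell_a, cell_b, endpoint t0 position of cell_a
    (ax, ay, az) and of cell_b (bx, by, bz), and the link vectors at the two
    timepoints (l0x..l0z, l1x..l1z). ``dt`` is the window length in hours.
    """

    frame: pd.DataFrame
    dt: float

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def l0(self) -> np.ndarray:
        return self.frame[["l0x", "l0y", "l0z"]].to_numpy(dtype=float)

    @property
    def l1(self) -> np.ndarray:
        return self.frame[["l1x", "l1y", "l1z"]].to_numpy(dtype=float)

    @property
    def endpoints_t0(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.frame[["ax", "ay", "az"]].to_numpy(dtype=float)
        b = self.frame[["bx", "by", "bz"]].to_numpy(dtype=float)
        return a, b


def match_links(
    links_t0: pd.DataFrame,
    cells_t0: pd.DataFrame,
    cells_t1: pd.DataFrame,
    track: pd.DataFrame,
    dt: float,
    require_adjacent_t1: bool = False,
    links_t1: pd.DataFrame | None = None,
) -> ConservedLinkSet:
    """Pair each conserved t0 link with its vector at t1.

    A link is conserved when both endpoints carry event "tracked" in the
    track map (daughters of divisions are excluded: the parent geometry is
    not comparable across the division). By default adjacency is required at
    t0 only — no intercalation is assumed over a 12-h window — but
    ``require_adjacent_t1=True`` additionally demands the pair be adjacent
    at t1 (``links_t1`` must then be given).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tracked = track[track["event"] == "tracked"]
    fwd = dict(zip(tracked["cell_id_t0"], tracked["cell_id_t1"]))
    if len(fwd) != len(tracked):
        raise ValueError("track map not injective on tracked pairs")

    _, p0 = _positions(cells_t0)
    pos0 = dict(zip(cells_t0["cell_id"], p0))
    _, p1 = _positions(cells_t1)
    pos1 = dict(zip(cells_t1["cell_id"], p1))

    adjacency_t1 = None
    if require_adjacent_t1:
        if links_t1 is None:
            raise ValueError("links_t1 required when require_adjacent_t1")
        adjacency_t1 = {
            frozenset((a, b)) for a, b in zip(links_t1["cell_a"], links_t1["cell_b"])
        }

    rows = []
    for a, b in zip(links_t0["cell_a"], links_t0["cell_b"]):
        if a not in fwd or b not in fwd:
            continue
        a1, b1 = fwd[a], fwd[b]
        if a1 not in pos1 or b1 not in pos1:
            continue
        if adjacency_t1 is not None and frozenset((a1, b1)) not in adjacency_t1:
            continue
        pa0, pb0 = pos0[a], pos0[b]
        l0 = pb0 - pa0
        l1 = pos1[b1] - pos1[a1]
        rows.append((a, b, *pa0, *pb0, *l0, *l1))
    frame = pd.DataFrame(
        rows,
        columns=[
            "cell_a", "cell_b",
            "ax", "ay", "az", "bx", "by", "bz",
            "l0x", "l0y", "l0z", "l1x", "l1y", "l1z",
        ],
    )
    return ConservedLinkSet(frame=frame, dt=float(dt))


def division_fraction(
    track: pd.DataFrame,
    cells_t0: pd.DataFrame,
    rudiment: str | None = None,
) -> float:
    """Percentage of t0 cells that divided over the window.

    100 × (number of parents with a division event) / (number of t0 cells),
    optionally restricted to one rudiment.
    """
    cells = cells_t0
    if rudiment is not None:
        cells = cells[cells["rudiment"] == rudiment]
    n0 = len(cells)
    if n0 == 0:
        raise ValueError("no cells at t0 in the requested rudiment")
    ids = set(cells["cell_id"])
    parents = set(
        track.loc[track["event"] == "divided", "cell_id_t0"]
    ) & ids
    return 100.0 * len(parents) / n0


def tracked_volume_expansion(
    volumes_t0: np.ndarray, volumes_t1: np.ndarray
) -> float:
    """Relative expansion (%) of the total tracked-cell volume over a window.

    100 × (ΣV_t1 − ΣV_t0) / ΣV_t0 over matched tracked cells.
    """
    v0 = np.asarray(volumes_t0, dtype=float)
    v1 = np.asarray(volumes_t1, dtype=float)
    if v0.shape != v1.shape:
        raise ValueError("volume lists must be matched 1:1")
    if len(v0) == 0 or (v0 <= 0).any() or (v1 <= 0).any():
        raise ValueError("volumes must be positive and non-empty")
    return 100.0 * (v1.sum() - v0.sum()) / v0.sum()


def tracked_volumes(
    cells_t0: pd.DataFrame,
    cells_t1: pd.DataFrame,
    track: pd.DataFrame,
    rudiment: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (V_t0, V_t1) arrays over tracked (non-dividing) cells."""
    tracked = track[track["event"] == "tracked"]
    c0 = cells_t0 if rudiment is None else cells_t0[cells_t0["rudiment"] == rudiment]
    v0map = dict(zip(c0["cell_id"], c0["volume_um3"]))
    v1map = dict(zip(cells_t1["cell_id"], cells_t1["volume_um3"]))
    v0, v1 = [], []
    for a, b in zip(tracked["cell_id_t0"], tracked["cell_id_t1"]):
        if a in v0map and b in v1map:
            v0.append(v0map[a])
            v1.append(v1map[b])
    return np.array(v0), np.array(v1)
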