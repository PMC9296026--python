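"""Shape-feature measurement and percentage-match scoring.

Five features are measured on the labelled jaw mesh, matching how outlines
are measured on exported lateral and ventral views: anterior Meckel's
cartilage (MC) length, depth and width, and posterior palatoquadrate (PQ)
length and depth. Lengths are anteroposterior (z) extents; depth is the
ventrodorsal (y) extent seen in the lateral view; width the mediolateral
(x) extent seen in the ventral view. Each feature is the axis-aligned
extent of the rudiment's labelled sub-mesh (proliferative + hypertrophic).

A prediction is scored per feature by the percentage match of change,

    PM = 100 · (m_pred − m_init) / (m_target − m_init),

binned as: PM < 10 % → no growth predicted; 10–70 % → undergrowth;
70–130 % → accurate growth; > 130 % → overgrowth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import VolumeMesh

#: feature id → (rudiment, axis index, view)
FEATURE_DEFS = {
    "MC_length": ("MC", 2, "either"),
    "MC_depth": ("MC", 1, "lateral"),
    "MC_width": ("MC", 0, "ventral"),
    "PQ_length": ("PQ", 2, "either"),
    "PQ_depth": ("PQ", 1, "lateral"),
}

CATEGORIES = ("no_growth", "undergrowth", "accurate", "overgrowth")

#: bin edges in percent; boundaries are closed on the accurate side
DEFAULT_BINS = (10.0, 70.0, 130.0)


@dataclass(frozen=True)
class ShapeFeatures:
    """The five measured features, μm."""

    MC_length: float
    MC_depth: float
    MC_width: float
    PQ_length: float
    PQ_depth: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_DEFS}


@dataclass(frozen=True)
class MatchResult:
    feature: str
    m_init: float
    m_target: float
    m_pred: float
    percentage_match: float | None
    category: str | None


def measure_features(
    mesh: VolumeMesh, view: str | None = None
) -> dict[str, float] | ShapeFeatures:
    """Measure rudiment extents on a labelled mesh.

    With ``view`` in {"lateral", "ventral"} only the features visible in
    that projection are returned (as a dict); otherwise all five are
    returned as :class:`ShapeFeatures`. Invariant under rigid translation.
    """
    vals = {}
    for name, (rud, axis, feat_view) in FEATURE_DEFS.items():
        if view is not None and feat_view not in ("either", view):
            continue
        nodes = mesh.rudiment_nodes(rud)
        if len(nodes) == 0:
            raise ValueError(f"rudiment {rud} is empty in this mesh")
        vals[name] = float(nodes[:, axis].max() - nodes[:, axis].min())
    if view is not None:
        return vals
    return ShapeFeatures(**vals)


def percentage_match(m_init: float, m_target: float, m_pred: float) -> float | None:
    """Signed percentage of the target change achieved by the prediction.

    Returns ``None`` when target equals initial (no change to match: the
    feature is unscoreable). The sign convention follows the raw formula, so
    a feature that should shrink but grew scores negative.
    """
    for v in (m_init, m_target, m_pred):
        if not math.isfinite(v):
            raise ValueError("feature measurements must be finite")
    if m_target == m_init:
        return None
    return 100.0 * (m_pred - m_init) / (m_target - m_init)


def classify(pm: float, bins: tuple[float, float, float] = DEFAULT_BINS) -> str:
    """Bin a percentage match into the four prediction-quality categories.

    Boundary values go to the higher-quality bin: exactly 10 % counts as
    undergrowth, exactly 70 % or 130 % as accurate.
    """
    if not math.isfinite(pm):
        raise ValueError("percentage match must be finite")
    lo, a, b = bins
    if pm < lo:
        return "no_growth"
    if pm < a:
        return "undergrowth"
    if pm <= b:
        return "accurate"
    return "overgrowth"


def score_features(
    init: ShapeFeatures,
    target: ShapeFeatures,
    pred: ShapeFeatures,
    bins: tuple[float, float, float] = DEFAULT_BINS,
) -> list[MatchResult]:
    out = []
    for name in FEATURE_DEFS:
        mi, mt, mp = (getattr(f, name) for f in (init, target, pred))
        pm = percentage_match(mi, mt, mp)
        out.append(
            MatchResult(
                feature=name, m_init=mi, m_target=mt, m_pred=mp,
                percentage_match=pm,
                category=None if pm is None else classify(pm, bins),
            )
        )
    return out


def scores_frame(results: list[MatchResult], **extra) -> pd.DataFrame:
    """Tidy scores table (one row per feature), with optional id columns."""
    df = pd.DataFrame([r.__dict__ for r in results])
    for k, v in extra.items():
        df.insert(0, k, v)
    return df


def summary_table(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Colour-code-style summary: feature × window category matrix."""
    allf = pd.concat(frames, ignore_index=True)
    return allf.pivot_table(
        index="feature", columns="window", values="category", aggfunc="first",
        sort=False,
    )
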