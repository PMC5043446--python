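"""Design ranking: hypervolume under the Pareto front (HVUPF) plus a
complexity-penalized selection score.

HVUPF is the Lebesgue measure of the region between the Pareto front and
the origin — the union over front points p of the boxes [0, p] in the
normalized objective space [0, 1]^d.  With all objectives minimized and
the origin optimal, a structure whose front lies closer to the origin
traces a smaller volume, so smaller HVUPF is better.  (This is the
origin-anchored reading, not the complement of the standard hypervolume
with reference point (1, ..., 1): a single front point at (0.5, 0.5) has
HVUPF 0.25.)

The selection score for a candidate structure combines min-max
normalized HVUPF and reaction-count complexity in an MDL-like trade-off
score = alpha * HV_norm + (1 - alpha) * C_norm (lower is better); ranks
are tie-averaged, and multi-task experiments are summarized by
per-structure median ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .optimize import ParetoFront

__all__ = [
    "hvupf",
    "box_union_volume",
    "score",
    "RankedDesign",
    "ScoreProfile",
    "rank_profile",
    "median_ranks",
]


def box_union_volume(points: np.ndarray) -> float:
    """Measure of the union of origin-anchored boxes [0, p] over points
    p in [0, 1]^d (d >= 1)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return 0.0
    if np.any(pts < 0) or np.any(pts > 1):
        raise ValueError("points must lie in the unit hypercube")
    return _union(pts[np.any(pts > 0, axis=1)])


def _union(pts: np.ndarray) -> float:
    if len(pts) == 0:
        return 0.0
    d = pts.shape[1]
    if d == 1:
        return float(pts.max())
    pts = _maximal(pts)
    if d == 2:
        return _union2(pts)
    # d >= 3: slice along the last coordinate
    zs = np.unique(pts[:, -1])[::-1]
    vol = 0.0
    for k, z in enumerate(zs):
        z_lo = zs[k + 1] if k + 1 < len(zs) else 0.0
        cross = pts[pts[:, -1] >= z][:, :-1]
        vol += (z - z_lo) * _union(cross)
    return float(vol)


def _maximal(pts: np.ndarray) -> np.ndarray:
    """Drop boxes contained in another box (points dominated in the
    componentwise-max sense); exact duplicates collapse to one."""
    pts = np.unique(pts, axis=0)
    if pts.shape[1] == 2:
        # sweep by x descending: keep points whose y exceeds the running max
        order = np.argsort(-pts[:, 0], kind="stable")
        keep, best_y = [], -1.0
        for i in order:
            if pts[i, 1] > best_y:
                keep.append(i)
                best_y = pts[i, 1]
        return pts[sorted(keep)]
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if np.any(ge & gt):
            keep[i] = False
    return pts[keep]


def _union2(pts: np.ndarray) -> float:
    """2-D union of origin boxes for a mutually maximal point set.

    After the containment filter y is strictly decreasing in x, so the
    union is the staircase: x_0*y_0 + sum_i (x_i - x_{i-1})*y_i."""
    order = np.argsort(pts[:, 0], kind="stable")
    x, y = pts[order, 0], pts[order, 1]
    vol = x[0] * y[0]
    for i in range(1, len(x)):
        vol += (x[i] - x[i - 1]) * y[i]
    return float(vol)


def hvupf(front: ParetoFront | np.ndarray) -> float:
    """Hypervolume under a Pareto front of minimized objectives in
    [0, 1]^d; empty fronts score worst (1.0)."""
    objs = front.objectives if isinstance(front, ParetoFront) else np.asarray(front, float)
    if objs.size == 0:
        return 1.0
    return box_union_volume(objs)


def score(hv_norm: float, c_norm: float, alpha: float) -> float:
    """MDL-like trade-off between normalized HVUPF and normalized
    structure complexity; lower is better."""
    for v, name in ((hv_norm, "hv_norm"), (c_norm, "c_norm"), (alpha, "alpha")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return alpha * hv_norm + (1.0 - alpha) * c_norm


@dataclass
class RankedDesign:
    structure_id: str
    hvupf: float
    complexity: int
    hv_norm: float = np.nan
    c_norm: float = np.nan
    score: float = np.nan
    rank: float = np.nan


@dataclass
class ScoreProfile:
    task: str
    designs: list[RankedDesign]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": d.structure_id,
                    "complexity": d.complexity,
                    "hvupf": d.hvupf,
                    "score": d.score,
                    "rank": d.rank,
                }
                for d in self.designs
            ]
        )

    def rank_of(self, structure_id: str) -> float:
        for d in self.designs:
            if d.structure_id == structure_id:
                return d.rank
        raise KeyError(structure_id)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def rank_profile(
    designs: list[tuple[str, float, int]], alpha: float = 0.5, task: str = ""
) -> ScoreProfile:
    """Rank candidate designs given (structure id, HVUPF, complexity).

    Both components are min-max normalized over the candidate set (a
    degenerate component is 0 for all); ranks are tie-averaged (tied
    scores share the mean of their rank positions) and the profile is
    ordered best (lowest score) first.
    """
    if not designs:
        raise ValueError("rank_profile needs at least one design")
    hv = np.array([d[1] for d in designs], dtype=float)
    cx = np.array([d[2] for d in designs], dtype=float)
    hvn, cxn = _minmax(hv), _minmax(cx)
    scores = np.array([score(h, c, alpha) for h, c in zip(hvn, cxn)])
    ranks = rankdata(scores, method="average")
    out = [
        RankedDesign(designs[i][0], hv[i], int(cx[i]), hvn[i], cxn[i], scores[i], ranks[i])
        for i in range(len(designs))
    ]
    out.sort(key=lambda d: (d.score, d.structure_id))
    return ScoreProfile(task=task, designs=out, alpha=alpha)


def median_ranks(profiles: list[ScoreProfile]) -> dict[str, float]:
    """Per-structure median rank across tasks ranking the same
    structure set (even counts take the mean of the middle two)."""
    if not profiles:
        raise ValueError("median_ranks needs at least one profile")
    ids = sorted(d.structure_id for d in profiles[0].designs)
    for p in profiles[1:]:
        if sorted(d.structure_id for d in p.designs) != ids:
            raise ValueError("profiles rank different structure sets")
    return {
        sid: float(np.median([p.rank_of(sid) for p in profiles])) for sid in ids
    }
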