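"""The dz disruption statistic for pathway trajectories.

For each pathway, a straight line is fitted by ordinary least squares to the
median z-scores at the pre-flight timepoints (signed days -92, -44, -3) and
extrapolated to the return day (+1). The statistic

    dz = z_observed(return) - z_predicted(return)

measures how much the pathway's return value departs from where its
pre-flight trend was heading: a large |dz| flags a pathway disrupted by the
flight itself, while dz near 0 marks a pathway merely continuing its
pre-flight trend. Pathways are ranked by signed dz from highest (most
disrupted upward) to lowest (continuing or disrupted downward); magnitude
ranking is available via ``absolute=True``.

dz is affine-equivariant: transforming a trajectory z -> a*z + b scales dz
by a and cancels b, so the ranking is invariant to the z-scale's origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coreg import PathwayTrajectory

__all__ = ["DzRecord", "fit_preflight_trend", "dz_score", "rank_by_dz", "dz_table"]


@dataclass(frozen=True)
class DzRecord:
    """Pre-flight fit and return-day deviation for one pathway."""

    pathway: str
    slope: float       # z-units per day
    intercept: float   # z-units at day 0
    z_pred_return: float
    z_obs_return: float
    dz: float
    rank: int | None = None


def fit_preflight_trend(
    times: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """OLS line through pre-flight (time, z) points; returns (slope, intercept).

    Closed-form normal equations: slope = S_xy / S_xx, intercept = ybar -
    slope * xbar. Requires >= 2 distinct negative times; exactly collinear
    input reproduces the line with zero residual.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(z, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and z must be 1-D and equal length")
    if (t >= 0).any():
        raise ValueError(f"non-preflight time in input: {t[t >= 0].tolist()}")
    if len(np.unique(t)) < 2:
        raise ValueError("need >=2 distinct pre-flight times to fit a trend")
    tbar = t.mean()
    ybar = y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    return slope, intercept


def dz_score(
    trajectory: PathwayTrajectory,
    return_day: int = 1,
    preflight_days: Sequence[int] = (-92, -44, -3),
) -> DzRecord:
    """Score one pathway trajectory: fit pre-flight, predict, subtract.

    ``return_day`` may name any post-launch timepoint present in the
    trajectory (e.g. a recovery day), in which case the deviation is scored
    against the same pre-flight fit.
    """
    have = dict(zip(trajectory.time_days, trajectory.median_z))
    missing = [d for d in [*preflight_days, return_day] if d not in have]
    if missing:
        raise ValueError(
            f"pathway {trajectory.pathway!r}: trajectory lacks required "
            f"timepoint day(s) {missing}"
        )
    slope, intercept = fit_preflight_trend(
        list(preflight_days), [have[d] for d in preflight_days]
    )
    z_pred = intercept + slope * return_day
    z_obs = float(have[return_day])
    return DzRecord(
        pathway=trajectory.pathway,
        slope=slope,
        intercept=intercept,
        z_pred_return=z_pred,
        z_obs_return=z_obs,
        dz=z_obs - z_pred,
    )


def rank_by_dz(records: Sequence[DzRecord], absolute: bool = False) -> list[DzRecord]:
    """Order records by descending dz (rank 1 = most disrupted upward).

    Ties break lexicographically by pathway name. ``absolute=True`` ranks by
    |dz| instead, mixing up- and down-disruptions.
    """
    if not records:
        raise ValueError("no records to rank")
    key = (lambda r: (-abs(r.dz), r.pathway)) if absolute else (
        lambda r: (-r.dz, r.pathway)
    )
    ordered = sorted(records, key=key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def dz_table(records: Sequence[DzRecord]) -> pd.DataFrame:
    """Ranked records as a tidy frame (the dz result table's column order)."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "slope": r.slope,
                "intercept": r.intercept,
                "z_pred": r.z_pred_return,
                "z_obs": r.z_obs_return,
                "dz": r.dz,
                "rank": r.rank,
            }
            for r in records
        ]
    )
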