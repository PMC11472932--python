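"""Exploration and variability metrics on trial series.

The central quantity is the lag-1 autocorrelation of endpoints along one
target axis: values near +1 indicate a random-walk-like drift of the aim
(exploration), values near 0 independent corrective reaching, and negative
values over-correction.  Variability is additionally conditioned on the
previous trial's outcome, since the generative model injects exploratory
noise only after a miss.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model_core import TrialSeries

__all__ = [
    "AXES",
    "project_to_target_frame",
    "lag1_pairs",
    "lag1_autocorrelation",
    "CohortSummary",
    "summarize_cohort",
    "OutcomeVariability",
    "delta_sd_by_outcome",
]

#: Axis labels: "minor" is target-frame x (task-relevant), "major" is y
#: (task-redundant).
AXES = ("minor", "major")
_AXIS_COLUMN = {"minor": 0, "major": 1}


def project_to_target_frame(
    raw_points, reach_angle: float, target_center
) -> np.ndarray:
    """Project lab-frame points into the target-aligned frame.

    ``reach_angle`` (degrees) is the counter-clockwise rotation of the
    target frame relative to the lab axes: at 0 the minor axis lies on
    lab x and the major axis on lab y (identity mapping); positive angles
    rotate both.  ``target_center`` is the target center in lab
    coordinates.  The returned frame has x along the minor axis, y along
    the major axis, origin at the target center.  Rigid,
    distance-preserving.
    """
    pts = np.atleast_2d(np.asarray(raw_points, dtype=float))
    center = np.asarray(target_center, dtype=float)
    if pts.shape[1] != 2 or center.shape != (2,):
        raise ValueError("expected 2-D points and a 2-D target center")
    if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(center))):
        raise ValueError("non-finite coordinates")
    theta = np.deg2rad(reach_angle)
    u_minor = np.array([np.cos(theta), np.sin(theta)])
    u_major = np.array([-np.sin(theta), np.cos(theta)])
    rel = pts - center
    return np.column_stack([rel @ u_minor, rel @ u_major])


def lag1_pairs(series) -> np.ndarray:
    """The (N-1, 2) array of consecutive-trial pairs the estimator consumes."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("lag-1 autocorrelation needs at least 3 values")
    return np.column_stack([x[:-1], x[1:]])


def lag1_autocorrelation(series, method: str = "pearson") -> float:
    """Lag-1 autocorrelation of a trial series.

    ``method='pearson'`` (default) is the product-moment correlation of the
    N-1 consecutive-trial pairs, each lagged copy standardized by its own
    mean and SD.  ``method='autocovariance'`` is the classical one-mean
    estimator, kept for sensitivity checks.  A constant series has no
    defined autocorrelation and yields ``nan``.
    """
    pairs = lag1_pairs(series)
    a, b = pairs[:, 0], pairs[:, 1]
    if method == "pearson":
        da, db = a - a.mean(), b - b.mean()
        denom = np.sqrt((da @ da) * (db @ db))
        if denom == 0.0:
            return float("nan")
        return float(np.clip((da @ db) / denom, -1.0, 1.0))
    if method == "autocovariance":
        x = np.asarray(series, dtype=float).ravel()
        d = x - x.mean()
        denom = d @ d
        if denom == 0.0:
            return float("nan")
        return float(np.clip((d[:-1] @ d[1:]) / denom, -1.0, 1.0))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CohortSummary:
    """Mean lag-1 ACF per (axis, condition, group[, experiment]) cell.

    ``cells`` holds one row per cell with columns
    ``experiment, group, condition, axis, mean_acf, n``; ``participant_acf``
    keeps the per-participant values behind those means (one row per
    participant x condition x axis), which the bootstrap resamples.
    """

    cells: pd.DataFrame
    participant_acf: Optional[pd.DataFrame] = None

    KEY = ["experiment", "group", "condition", "axis"]

    def __post_init__(self) -> None:
        missing = set(self.KEY + ["mean_acf", "n"]) - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells missing columns {sorted(missing)}")
        if (self.cells["n"] < 1).any():
            raise ValueError("every summary cell must be non-empty")
        acf = self.cells["mean_acf"]
        if ((acf < -1) | (acf > 1)).any():
            raise ValueError("mean ACF outside [-1, 1]")

    def subset(self, **where) -> "CohortSummary":
        mask = np.ones(len(self.cells), dtype=bool)
        for key, value in where.items():
            values = [value] if isinstance(value, str) else list(value)
            mask &= self.cells[key].isin(values).to_numpy()
        part = None
        if self.participant_acf is not None:
            pmask = np.ones(len(self.participant_acf), dtype=bool)
            for key, value in where.items():
                values = [value] if isinstance(value, str) else list(value)
                pmask &= self.participant_acf[key].isin(values).to_numpy()
            part = self.participant_acf[pmask].reset_index(drop=True)
        return CohortSummary(self.cells[mask].reset_index(drop=True), part)

    def cell_means(self) -> dict[tuple, float]:
        return {
            tuple(row[k] for k in self.KEY): row["mean_acf"]
            for _, row in self.cells.iterrows()
        }

    @classmethod
    def from_participants(cls, participant_acf: pd.DataFrame) -> "CohortSummary":
        """Cell means from a per-participant ACF table (nan ACFs excluded)."""
        valid = participant_acf[np.isfinite(participant_acf["acf"])]
        if valid.empty:
            raise ValueError("no participant with a defined ACF")
        grouped = (
            valid.groupby(cls.KEY, as_index=False, sort=True)
            .agg(mean_acf=("acf", "mean"), n=("acf", "size"))
        )
        return cls(grouped, participant_acf.reset_index(drop=True))


def summarize_cohort(series_set: Iterable[TrialSeries]) -> CohortSummary:
    """Per-participant lag-1 ACFs, then unweighted cell means.

    Participants whose ACF is undefined (constant series) are excluded from
    the cell mean but remain visible in ``participant_acf`` as ``nan``.
    """
    rows = []
    for series in series_set:
        pts = series.endpoints()
        for axis in AXES:
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "experiment": series.experiment,
                    "group": series.group,
                    "condition": series.condition,
                    "axis": axis,
                    "acf": lag1_autocorrelation(pts[:, _AXIS_COLUMN[axis]]),
                }
            )
    if not rows:
        raise ValueError("empty series set")
    return CohortSummary.from_participants(pd.DataFrame(rows))


@dataclass(frozen=True)
class OutcomeVariability:
    """SD of the trial-to-trial endpoint change, split by the earlier trial's outcome.

    Cells with fewer than two usable changes are ``None`` (absent), never
    zero-filled.  Units cm; sample (n-1) denominators.
    """

    sd_hit_minor: Optional[float]
    sd_hit_major: Optional[float]
    sd_miss_minor: Optional[float]
    sd_miss_major: Optional[float]


def _sd_or_none(values: np.ndarray) -> Optional[float]:
    if values.size < 2:
        return None
    return float(np.std(values, ddof=1))


def delta_sd_by_outcome(series: TrialSeries) -> OutcomeVariability:
    """Outcome-conditioned trial-to-trial variability for one condition block.

    Each change ``x[t+1] - x[t]`` is classified by the outcome of the earlier
    trial t; changes never cross condition blocks (a series is one block by
    construction).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 trials")
    pts = series.endpoints()
    rewards = series.rewards()[:-1]
    deltas = np.diff(pts, axis=0)
    hit = rewards == 1
    return OutcomeVariability(
        sd_hit_minor=_sd_or_none(deltas[hit, 0]),
        sd_hit_major=_sd_or_none(deltas[hit, 1]),
        sd_miss_minor=_sd_or_none(deltas[~hit, 0]),
        sd_miss_major=_sd_or_none(deltas[~hit, 1]),
    )
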