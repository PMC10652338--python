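"""Cumulus-expansion endpoints and time-lapse morphokinetics.

Endpoint analysis takes pre/post expansion areas and the four
clock-position thickness readings per COC and forms post-minus-pre deltas
(difference-between-differences input).  Time-lapse analysis converts
hourly edge-distance series into 1 h and 4 h velocity profiles (um/min)
plus an overall expansion rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from cocmatrix import stats as _stats

__all__ = [
    "WINDOWS_H",
    "ExpansionRecord",
    "DistanceSeries",
    "VelocityProfile",
    "velocity",
    "profile",
    "expansion_deltas",
    "compare_groups",
]

#: 4 h analysis windows, labelled by the hours of the member 1 h intervals
WINDOWS_H = (
    ("1-4 h", 0.0, 4.0),
    ("5-8 h", 4.0, 8.0),
    ("9-12 h", 8.0, 12.0),
    ("13-16 h", 12.0, 16.0),
)


@dataclass(frozen=True)
class ExpansionRecord:
    """Pre/post measurements for a single COC."""

    coc_id: str
    mouse_id: str
    group: str
    pre_area_mm2: float
    post_area_mm2: float
    pre_thickness_um: tuple[float, float, float, float]
    post_thickness_um: tuple[float, float, float, float]
    score: int

    def __post_init__(self) -> None:
        if self.pre_area_mm2 <= 0 or self.post_area_mm2 <= 0:
            raise ValueError("areas must be positive")
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError("score must be an integer in 0..4")
        for tp in (self.pre_thickness_um, self.post_thickness_um):
            if len(tp) != 4:
                raise ValueError("exactly 4 thickness readings per timepoint "
                                 "(3, 6, 9 and 12 o'clock)")


@dataclass(frozen=True)
class DistanceSeries:
    """Hourly cumulus edge distances for one COC.

    Series may truncate early when the cumulus layer expands beyond the
    well limits (typically >= 12 h).
    """

    coc_id: str
    times_h: np.ndarray
    distances_um: np.ndarray
    mouse_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        d = np.asarray(self.distances_um, dtype=float)
        if t.size != d.size:
            raise ValueError("times and distances must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "distances_um", d)


@dataclass(frozen=True)
class VelocityProfile:
    """Velocities in um/min at 1 h and 4 h resolution.

    ``v1h`` maps each interval's end time (h) to its velocity; ``v4h``
    maps window labels to the mean of their member interval velocities.
    """

    coc_id: str
    v1h: dict[float, float]
    v4h: dict[str, float]
    overall_rate: float
    peak_window: str


def velocity(d1: float, d2: float, t1_min: float, t2_min: float) -> float:
    """Expansion velocity (distance2 - distance1)/(time2 - time1) in um/min.

    Negative values (retraction) are returned unchanged.
    """
    if t2_min <= t1_min:
        raise ValueError("second time point must be after the first")
    return (d2 - d1) / (t2_min - t1_min)


def profile(
    series: DistanceSeries,
    window_mode: Literal["mean_of_hourly", "endpoint"] = "mean_of_hourly",
) -> VelocityProfile:
    """Velocity profile of a distance series.

    ``mean_of_hourly`` (default) computes each 4 h window as the mean of
    its member interval velocities; ``endpoint`` uses the difference
    quotient between the window's boundary distances.  With exactly hourly
    sampling the two coincide (telescoping identity).
    """
    t = series.times_h
    d = series.distances_um
    if t.size < 2:
        raise ValueError("need at least 2 time points")

    v1h: dict[float, float] = {}
    for i in range(t.size - 1):
        v1h[float(t[i + 1])] = velocity(d[i], d[i + 1], t[i] * 60.0, t[i + 1] * 60.0)

    v4h: dict[str, float] = {}
    for label, lo, hi in WINDOWS_H:
        if window_mode == "mean_of_hourly":
            members = [v for end, v in v1h.items() if lo < end <= hi]
            if members:
                v4h[label] = float(np.mean(members))
        else:
            inside = (t > lo) & (t <= hi)
            if not inside.any():
                continue
            i_hi = np.nonzero(inside)[0][-1]
            at_or_before = np.nonzero(t <= lo)[0]
            i_lo = at_or_before[-1] if at_or_before.size else None
            if i_lo is None or i_hi <= i_lo:
                continue
            v4h[label] = velocity(d[i_lo], d[i_hi], t[i_lo] * 60.0, t[i_hi] * 60.0)

    overall = velocity(d[0], d[-1], t[0] * 60.0, t[-1] * 60.0)
    peak = max(v4h, key=v4h.get) if v4h else ""
    return VelocityProfile(
        coc_id=series.coc_id, v1h=v1h, v4h=v4h, overall_rate=overall,
        peak_window=peak,
    )


def expansion_deltas(rec: ExpansionRecord) -> tuple[float, float]:
    """Post-minus-pre change in area (mm2) and mean layer thickness (um)."""
    delta_area = rec.post_area_mm2 - rec.pre_area_mm2
    delta_thick = float(np.mean(rec.post_thickness_um)) - float(
        np.mean(rec.pre_thickness_um)
    )
    return delta_area, delta_thick


_METRICS = ("area", "thickness", "score")


def _metric_value(rec: ExpansionRecord, metric: str) -> float:
    if metric == "area":
        return expansion_deltas(rec)[0]
    if metric == "thickness":
        return expansion_deltas(rec)[1]
    if metric == "score":
        return float(rec.score)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def compare_groups(
    records: Sequence[ExpansionRecord],
    metric: Literal["area", "thickness", "score"] = "area",
    nested: bool = False,
) -> _stats.TestResult:
    """Two-group comparison of post-minus-pre deltas (or scores).

    Uses the normality-gated t / Mann-Whitney selection, or the
    cluster-aware nested t-test on per-mouse means when ``nested``.
    """
    df = pd.DataFrame(
        {
            "value": [_metric_value(r, metric) for r in records],
            "mouse": [r.mouse_id for r in records],
            "group": [r.group for r in records],
        }
    )
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a = df.loc[df["group"] == groups[0], "value"]
    b = df.loc[df["group"] == groups[1], "value"]
    if a.empty or b.empty:
        raise ValueError("a group is empty")
    if nested:
        sample = _stats.GroupedSample(
            values=df["value"].to_numpy(),
            cluster_id=df["mouse"].to_numpy(),
            group=df["group"].to_numpy(),
        )
        return _stats.nested_t_test(sample)
    return _stats.choose_two_group_test(a.to_numpy(), b.to_numpy())
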