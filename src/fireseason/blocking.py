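"""Persistent positive anomaly (blocking proxy) detection.

A blocking proxy event is a contiguous region where 500-hPa geopotential
heights exceed one local standard deviation above the seasonal
climatological mean, persisting for a minimum number of days, whose
footprint reaches a minimum area at some point in its evolution.  Daily
anomaly components are linked through time by spatial overlap; splits
and merges are resolved by largest-overlap inheritance, with the other
branches spawning new events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = ["BlockingConfig", "PpaEvent", "anomaly_field", "detect_events", "blocking_day_map"]


@dataclass(frozen=True)
class BlockingConfig:
    sd_threshold: float = 1.0
    min_days: int = 5
    min_area_km2: float = 100_000.0
    season_months: tuple[int, int] = (4, 10)  # April–October
    connectivity: int = 8
    overlap_min_cells: int = 1

    def __post_init__(self):
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")
        if self.min_area_km2 <= 0:
            raise ValueError("min_area_km2 must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class PpaEvent:
    """One tracked positive-anomaly event."""

    event_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    day_masks: list[np.ndarray] = field(repr=False, default_factory=list)
    area_trajectory_km2: list[float] = field(default_factory=list)

    @property
    def duration(self) -> int:
        return len(self.day_masks)

    @property
    def max_area_km2(self) -> float:
        return max(self.area_trajectory_km2) if self.area_trajectory_km2 else 0.0


def anomaly_field(
    heights: xr.DataArray,
    baseline_years: tuple[int, int] = (1991, 2020),
    smooth_months: int = 1,
) -> xr.DataArray:
    """z-score of daily heights against a calendar-month climatology.

    The "seasonal" climatological mean and SD of each cell are taken per
    calendar month over the baseline years (``smooth_months=3`` pools
    each month with its neighbours instead).  Cells/months with zero SD
    are masked.
    """
    if smooth_months not in (1, 3):
        raise ValueError("smooth_months must be 1 or 3")
    times = pd.DatetimeIndex(heights["time"].values)
    in_base = (times.year >= baseline_years[0]) & (times.year <= baseline_years[1])
    if not in_base.any():
        raise ValueError(f"no data within baseline years {baseline_years}")
    months = times.month.values

    z = np.full(heights.shape, np.nan)
    hv = heights.transpose("time", "lat", "lon").values
    for m in range(1, 13):
        sel_out = months == m
        if not sel_out.any():
            continue
        if smooth_months == 1:
            pool = sel_out & in_base
        else:
            neighbours = {(m - 2) % 12 + 1, m, m % 12 + 1}
            pool = np.isin(months, list(neighbours)) & in_base
        if not pool.any():
            continue
        mean = hv[pool].mean(axis=0)
        sd = hv[pool].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z[sel_out] = (hv[sel_out] - mean) / np.where(sd > 0, sd, np.nan)
    return xr.DataArray(z, coords=heights.coords, dims=heights.dims, name="z")


def _label(day_mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    return ndimage.label(day_mask, structure=structure)


def detect_events(
    z: xr.DataArray,
    config: BlockingConfig = BlockingConfig(),
    cell_areas_km2: np.ndarray | None = None,
) -> list[PpaEvent]:
    """Track contiguous above-threshold regions into qualifying events.

    Only days inside the season window are considered.  Returns events
    meeting both the persistence (``min_days``) and the maximum-footprint
    (``min_area_km2``) criteria, ordered by start date.
    """
    times = pd.DatetimeIndex(z["time"].values)
    zv = z.transpose("time", "lat", "lon").values
    if cell_areas_km2 is None:
        cell_areas_km2 = np.ones(zv.shape[1:])
    areas = np.asarray(cell_areas_km2, dtype=float)

    m0, m1 = config.season_months
    in_season = (times.month >= m0) & (times.month <= m1)

    open_events: dict[int, PpaEvent] = {}
    finished: list[PpaEvent] = []
    next_id = 0
    prev_labels = np.zeros(zv.shape[1:], dtype=int)
    prev_owner: dict[int, int] = {}  # previous-day component label -> event id

    for i, t in enumerate(times):
        day = np.nan_to_num(zv[i], nan=-np.inf) > config.sd_threshold
        if not in_season[i]:
            day = np.zeros_like(day)
        labels, ncomp = _label(day, config.connectivity)

        owner: dict[int, int] = {}
        claimed_events: dict[int, tuple[int, int]] = {}  # event id -> (overlap, comp)
        for comp in range(1, ncomp + 1):
            comp_mask = labels == comp
            # overlap with yesterday's components, attributed to their events
            overlap_by_event: dict[int, int] = {}
            prev_hits = prev_labels[comp_mask]
            for lbl, cnt in zip(*np.unique(prev_hits[prev_hits > 0], return_counts=True)):
                ev = prev_owner.get(int(lbl))
                if ev is not None:
                    overlap_by_event[ev] = overlap_by_event.get(ev, 0) + int(cnt)
            best_ev, best_ov = None, 0
            for ev, ov in sorted(overlap_by_event.items()):
                if ov >= config.overlap_min_cells and ov > best_ov:
                    best_ev, best_ov = ev, ov
            # largest-overlap inheritance: an event continues into the
            # component that shares the most cells; other claimants spawn anew
            if best_ev is not None:
                held = claimed_events.get(best_ev)
                if held is None or best_ov > held[0]:
                    if held is not None:
                        owner[held[1]] = -1  # displaced claimant becomes new
                    claimed_events[best_ev] = (best_ov, comp)
                    owner[comp] = best_ev
                    continue
            owner[comp] = -1

        # finalize events not continued today
        continued = {ev for ev, (_, comp) in claimed_events.items() if owner.get(comp) == ev}
        for ev in list(open_events):
            if ev not in continued:
                finished.append(open_events.pop(ev))

        new_owner: dict[int, int] = {}
        for comp in range(1, ncomp + 1):
            comp_mask = labels == comp
            ev = owner.get(comp, -1)
            if ev == -1:
                ev = next_id
                next_id += 1
                open_events[ev] = PpaEvent(event_id=ev, start=t, end=t)
            event = open_events[ev]
            if event.day_masks and event.end == t:
                # merge: second component joining the same event on one day
                event.day_masks[-1] = event.day_masks[-1] | comp_mask
                event.area_trajectory_km2[-1] = float(areas[event.day_masks[-1]].sum())
            else:
                event.day_masks.append(comp_mask.copy())
                event.area_trajectory_km2.append(float(areas[comp_mask].sum()))
                event.end = t
            new_owner[comp] = ev

        prev_labels = labels
        prev_owner = new_owner

    finished.extend(open_events.values())
    qualifying = [
        e
        for e in finished
        if e.duration >= config.min_days and e.max_area_km2 >= config.min_area_km2
    ]
    qualifying.sort(key=lambda e: (e.start, e.event_id))
    return qualifying


def blocking_day_map(
    events: list[PpaEvent],
    grid_shape: tuple[int, int],
    season_months: tuple[int, int] = (4, 10),
) -> np.ndarray:
    """Per-cell count of days under any qualifying event, in-season only."""
    counts = np.zeros(grid_shape, dtype=int)
    m0, m1 = season_months
    for event in events:
        day = event.start
        for mask in event.day_masks:
            if m0 <= day.month <= m1:
                counts[mask] += 1
            day = day + pd.Timedelta(days=1)
    return counts
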