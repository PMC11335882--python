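"""Snowmelt timing and flash-drought (rapid soil drying) statistics.

Snowmelt timing at a location is the first day of the longest snow-free
run of the calendar year (ties broken toward the earliest run); the
departure is the difference from a multi-year baseline mean.  Rapid
drought onset is the maximum 14-day endpoint-to-endpoint reduction in
root-zone soil moisture over a fixed spring search window, with the
midpoint of the (earliest) maximal window as the onset date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DryingResult", "snowmelt_timing", "melt_departure", "max_window_drying"]


@dataclass(frozen=True)
class DryingResult:
    max_drying: float  # kg m⁻², >= 0
    mid_day: int  # day index of the maximal window's midpoint
    window_days: int = 14


def snowmelt_timing(snow_flags: np.ndarray) -> tuple[int, bool]:
    """First day (1-based) of the longest snow-free run of the year.

    ``snow_flags`` is a full-year boolean series, True = snow covered.
    Returns ``(day, ok)``; a never-snow-free series yields ``(0, False)``
    and a never-snow-covered one ``(1, False)`` (degenerate but usable).
    Runs do not wrap across the year boundary.
    """
    snow = np.asarray(snow_flags, dtype=bool)
    free = ~snow
    if not free.any():
        return 0, False
    # run-length encode the snow-free stretches
    edges = np.diff(np.concatenate(([0], free.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    best = int(starts[np.argmax(lengths)])  # argmax takes the earliest maximum
    return best + 1, bool(snow.any())


def melt_departure(target_melt: np.ndarray, baseline_melts: np.ndarray) -> np.ndarray:
    """Departure (days) of target melt day from the baseline mean.

    ``baseline_melts`` has years on axis 0.  Negative = earlier melt.
    Cells with no valid baseline (all-NaN) are returned as NaN.
    """
    target = np.asarray(target_melt, dtype=float)
    base = np.asarray(baseline_melts, dtype=float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(base, axis=0)
    return target - mean


def max_window_drying(
    series: np.ndarray,
    window_days: int = 14,
    search_start: int = 0,
    search_stop: int | None = None,
) -> DryingResult:
    """Maximum soil-moisture reduction over a sliding window.

    ``series`` is a daily root-zone soil-moisture series (kg m⁻²);
    ``search_start``/``search_stop`` index the admissible interval (stop
    exclusive; default the whole series) and whole windows must fit
    inside it.  Drying is measured endpoint-to-endpoint, day t minus day
    t + window_days − 1, floored at 0 (wetting reports 0); ties take the
    earliest window.  The midpoint is ``t + (window_days - 1) // 2``.
    """
    x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"series has gaps at indices {np.flatnonzero(np.isnan(x)).tolist()}"
        )
    stop = len(x) if search_stop is None else search_stop
    if stop - search_start < window_days:
        raise ValueError("search interval shorter than the window")
    seg_start = x[search_start : stop - window_days + 1]
    seg_end = x[search_start + window_days - 1 : stop]
    drops = seg_start - seg_end
    best = int(np.argmax(drops))  # earliest maximal window
    max_drying = float(max(drops[best], 0.0))
    mid = search_start + best + (window_days - 1) // 2
    return DryingResult(max_drying=max_drying, mid_day=mid, window_days=window_days)
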