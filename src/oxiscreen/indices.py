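"""Conventional oximetry indices: ODI3/ODI4, CT90 and summary saturations.

The oxygen desaturation index (ODI) is the hourly rate of desaturation
events — falls of at least 3 % (ODI3) or 4 % (ODI4) below the running
baseline with subsequent resaturation. Devices differ in the exact scoring
rule; the detector here follows common sleep-scoring conventions and every
constant is configurable: the baseline is a trailing moving maximum (default
120 s), an event triggers when the saturation deficit reaches the threshold,
and ends when the deficit recovers to within 1 % of baseline or after a
maximum event length (default 5 min). Trigger and release thresholds are
asymmetric (hysteresis), which also guarantees that every 4 %-event lies
inside a 3 %-event, so ODI4 can never exceed ODI3.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, stats as sct

__all__ = [
    "DesaturationEvent",
    "OximetryIndices",
    "detect_desaturations",
    "odi",
    "ct90_and_stats",
    "compute_indices",
]

BASELINE_WINDOW_S = 120
MAX_EVENT_S = 300
RESAT_MARGIN = 1.0  # event ends once deficit <= this (% below baseline)


@dataclass
class DesaturationEvent:
    start: int   # sample index of onset
    nadir: int   # sample index of minimum saturation
    end: int     # sample index of recovery (inclusive)


@dataclass
class OximetryIndices:
    odi3: float
    odi4: float
    ct90: float
    spo2_basal: float
    spo2_min: float
    spo2_mean: float

    def to_dict(self) -> dict:
        return asdict(self)


def _trailing_max(x: np.ndarray, window: int) -> np.ndarray:
    """Running maximum over the trailing ``window`` samples (inclusive)."""
    # shift the filter window so its rightmost element is the current sample
    return ndimage.maximum_filter1d(x, size=window, origin=-((window - 1) // 2),
                                    mode="nearest")


def detect_desaturations(
    x: np.ndarray,
    drop_threshold: float = 3.0,
    baseline_window_s: int = BASELINE_WINDOW_S,
    max_event_s: int = MAX_EVENT_S,
    resat_margin: float = RESAT_MARGIN,
    smooth_s: int = 5,
) -> list[DesaturationEvent]:
    """Find desaturation events of at least ``drop_threshold`` % below baseline.

    Returns non-overlapping, time-ordered events. Operates on a preprocessed
    1-Hz series. A short median prefilter (``smooth_s`` samples, default 5)
    suppresses measurement noise before baseline and deficit computation, as
    automated scoring software commonly does; set it to 1 to disable.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n == 0:
        return []
    if smooth_s > 1 and n > smooth_s:
        x = ndimage.median_filter(x, size=smooth_s, mode="nearest")
    baseline = _trailing_max(x, baseline_window_s)
    deficit = baseline - x

    events: list[DesaturationEvent] = []
    t = 0
    while t < n:
        if deficit[t] >= drop_threshold:
            start = t
            end = t
            while end + 1 < n and deficit[end + 1] > resat_margin and \
                    (end + 1 - start) < max_event_s:
                end += 1
            nadir = start + int(np.argmin(x[start : end + 1]))
            events.append(DesaturationEvent(start, nadir, end))
            t = end + 1
        else:
            t += 1
    return events


def odi(x: np.ndarray, drop_threshold: float, duration_hours: float | None = None,
        **kwargs) -> float:
    """Desaturation events per hour of recording."""
    x = np.asarray(x, float)
    if duration_hours is None:
        duration_hours = (len(x) - 1) / 3600.0
    if duration_hours <= 0:
        raise ValueError("recording duration must be positive")
    events = detect_desaturations(x, drop_threshold, **kwargs)
    return len(events) / duration_hours


def ct90_and_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    """CT90 (% of time below 90 % SpO2), basal (modal), min and mean SpO2."""
    x = np.asarray(x, float)
    if len(x) == 0:
        raise ValueError("empty signal")
    ct90 = 100.0 * float(np.count_nonzero(x < 90.0)) / len(x)
    basal = float(sct.mode(np.round(x).astype(int), keepdims=False).mode)
    return ct90, basal, float(x.min()), float(x.mean())


def compute_indices(x: np.ndarray, duration_hours: float | None = None,
                    **kwargs) -> OximetryIndices:
    """All conventional indices for one preprocessed recording."""
    ct90, basal, mn, mean = ct90_and_stats(x)
    return OximetryIndices(
        odi3=odi(x, 3.0, duration_hours, **kwargs),
        odi4=odi(x, 4.0, duration_hours, **kwargs),
        ct90=ct90, spo2_basal=basal, spo2_min=mn, spo2_mean=mean,
    )
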