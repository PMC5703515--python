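"""Artifact removal and gap bridging for 1-Hz SpO2 series.

Portable oximetry is contaminated by probe disconnections and movement
artifacts. Three rules clean the series: (i) zero samples are removed,
(ii) saturations below 20 % are removed (physiologically impossible at the
finger), and (iii) sample-to-sample changes of 4 %/s or more mark transient
artifactual dips, whose samples are removed. After removal the remaining
valid sections are concatenated; where the junction itself would introduce a
jump of >= 4 %/s, a linear ramp is interpolated so that no non-natural change
enters the series.

The delta rule does not by itself say which side of a >= 4 %/s step is the
artifact. A transient dip is a short excursion; a genuine desaturation (deep
in COPD, but never instantaneous) persists. We therefore split the signal at
every >= 4 %/s step into internally consistent runs and drop runs shorter
than ``min_consistent_s`` seconds that sit next to such a step; long runs on
both sides of a step are both kept (a physiological level shift) and the
seam is ramped.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import SpO2Recording

__all__ = [
    "PreprocessReport",
    "UnusableRecordingError",
    "remove_artifacts",
    "bridge_gaps",
    "preprocess",
]

#: steps of this magnitude or larger (in %/s) are non-natural
DELTA_LIMIT = 4.0
#: samples strictly below this saturation are artifacts
LOW_LIMIT = 20.0
#: a run shorter than this (seconds) adjacent to a >=4 %/s step is transient
MIN_CONSISTENT_S = 30


class UnusableRecordingError(ValueError):
    """Raised when artifact removal leaves no usable signal."""


@dataclass
class PreprocessReport:
    n_zero_removed: int = 0
    n_below20_removed: int = 0
    n_delta_removed: int = 0
    n_gaps_bridged: int = 0
    n_interpolated_samples: int = 0
    fraction_removed: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _split_runs(x: np.ndarray, delta_limit: float) -> list[np.ndarray]:
    """Split a contiguous stretch into maximal runs with internal steps < limit."""
    if len(x) == 0:
        return []
    cuts = np.flatnonzero(np.abs(np.diff(x)) >= delta_limit) + 1
    return np.split(x, cuts)


def remove_artifacts(
    rec: SpO2Recording | np.ndarray,
    delta_limit: float = DELTA_LIMIT,
    low_limit: float = LOW_LIMIT,
    min_consistent_s: int = MIN_CONSISTENT_S,
) -> tuple[list[np.ndarray], PreprocessReport]:
    """Apply the three artifact rules; return kept segments and a report.

    Missing samples are treated like zeros (removed, later bridged). The
    result is a list of clean segments in time order, to be joined by
    :func:`bridge_gaps`. Raises :class:`UnusableRecordingError` if nothing
    survives.
    """
    x = rec.samples if isinstance(rec, SpO2Recording) else np.asarray(rec, float)
    n = len(x)
    report = PreprocessReport()

    missing = ~np.isfinite(x)
    zero = np.isfinite(x) & (x == 0)
    low = np.isfinite(x) & (x > 0) & (x < low_limit)
    report.n_zero_removed = int(np.count_nonzero(missing | zero))
    report.n_below20_removed = int(np.count_nonzero(low))
    drop = missing | zero | low

    # contiguous stretches of surviving samples
    stretches: list[np.ndarray] = []
    keep_idx = np.flatnonzero(~drop)
    if keep_idx.size:
        brk = np.flatnonzero(np.diff(keep_idx) > 1) + 1
        stretches = [x[idx] for idx in np.split(keep_idx, brk)]

    # Delta rule within each stretch: split at >=4 %/s steps into internally
    # consistent runs, then repeatedly remove the shorter side of each step —
    # unless both sides persist for >= min_consistent_s seconds, in which case
    # the step is a physiological level shift and both runs are kept (the
    # seam is ramped later by bridge_gaps).
    segments: list[np.ndarray] = []
    for stretch in stretches:
        runs = _split_runs(stretch, delta_limit)
        i = 0
        while i < len(runs) - 1:
            a, b = runs[i], runs[i + 1]
            if abs(b[0] - a[-1]) < delta_limit:  # seam healed by a removal
                runs[i : i + 2] = [np.concatenate([a, b])]
                i = max(i - 1, 0)
            elif len(a) >= min_consistent_s and len(b) >= min_consistent_s:
                i += 1  # level shift: keep both sides
            else:
                short = i if len(a) < len(b) else i + 1  # tie: drop the arriving run
                report.n_delta_removed += len(runs[short])
                del runs[short]
                i = max(i - 1, 0)
        segments.extend(runs)

    segments = [s for s in segments if len(s)]
    if not segments:
        raise UnusableRecordingError("recording empty after artifact removal")
    n_kept = sum(len(s) for s in segments)
    report.fraction_removed = (n - n_kept) / n if n else 0.0
    return segments, report


def bridge_gaps(
    segments: list[np.ndarray],
    delta_limit: float = DELTA_LIMIT,
    report: PreprocessReport | None = None,
) -> np.ndarray:
    """Concatenate clean segments, ramping seams that would jump >= 4 %/s.

    At each seam with |step| >= ``delta_limit`` the smallest number k of
    equally spaced samples is inserted such that every sub-step is strictly
    below the limit (k is the least integer with |step|/(k+1) < limit).
    """
    if not segments:
        raise UnusableRecordingError("no segments to bridge")
    out = [segments[0]]
    for seg in segments[1:]:
        gap = abs(seg[0] - out[-1][-1])
        if gap >= delta_limit:
            k = int(np.floor(gap / delta_limit))
            if gap / (k + 1) >= delta_limit:  # exact multiple of the limit
                k += 1
            ramp = np.linspace(out[-1][-1], seg[0], k + 2)[1:-1]
            out.append(ramp)
            if report is not None:
                report.n_gaps_bridged += 1
                report.n_interpolated_samples += k
        out.append(seg)
    return np.concatenate(out)


def preprocess(
    rec: SpO2Recording | np.ndarray,
    delta_limit: float = DELTA_LIMIT,
    low_limit: float = LOW_LIMIT,
    min_consistent_s: int = MIN_CONSISTENT_S,
) -> tuple[np.ndarray, PreprocessReport]:
    """Full cleaning pipeline: artifact removal then gap bridging."""
    segments, report = remove_artifacts(rec, delta_limit, low_limit, min_consistent_s)
    clean = bridge_gaps(segments, delta_limit, report)
    return clean, report
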