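"""Trace preprocessing, calcium-event detection and activity statistics.

The preprocessing step converts raw fluorescence into dF/F0 fluctuations
against a running-percentile baseline; event detection finds oscillations
as excursions above a robust (MAD-based) noise threshold and measures
their duration at a configurable fraction of peak height; the activity
summary reports the three per-culture statistics: percentage of active
cells, oscillation frequency (per active cell, per minute) and mean
event duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter, uniform_filter1d

__all__ = [
    "TraceMatrix",
    "ActivitySummary",
    "EVENT_COLUMNS",
    "preprocess",
    "detect_events",
    "summarize_activity",
    "extract_rois",
]

EVENT_COLUMNS = ["cell_id", "onset_s", "offset_s", "duration_s", "amplitude"]


@dataclass(frozen=True)
class TraceMatrix:
    """Cells x frames fluorescence (or fluctuation) matrix on a uniform
    time grid."""

    cell_ids: np.ndarray   # (n,)
    times_s: np.ndarray    # (T,)
    values: np.ndarray     # (n, T)

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x frames)")
        if self.values.shape != (len(self.cell_ids), len(self.times_s)):
            raise ValueError("values shape inconsistent with ids/times")
        if len(self.times_s) < 2:
            raise ValueError("need at least 2 frames")
        dt = np.diff(self.times_s)
        if np.any(np.abs(dt - dt[0]) > 1e-9):
            raise ValueError("frame times must be uniformly spaced")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def recording_length_s(self) -> float:
        return float(len(self.times_s)) / self.sampling_rate_hz


@dataclass(frozen=True)
class ActivitySummary:
    """Per-recording calcium-activity statistics.

    ``frequency_per_min`` averages over active cells only (cells with at
    least one oscillation); statistics that are undefined on an empty
    event table are reported as NaN, never as zero.
    """

    active_cells_pct: float
    frequency_per_min: float
    mean_duration_s: float
    n_cells: int
    recording_length_s: float

    def to_dict(self) -> dict:
        return {
            "active_cells_pct": self.active_cells_pct,
            "frequency_per_min": self.frequency_per_min,
            "mean_duration_s": self.mean_duration_s,
            "n_cells": self.n_cells,
            "recording_length_s": self.recording_length_s,
        }


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    traces: TraceMatrix,
    baseline_window_s: float = 60.0,
    baseline_percentile: float = 20.0,
) -> TraceMatrix:
    """Detrend and normalize: dF/F0 against a running-percentile baseline.

    F0(t) is the ``baseline_percentile``-th percentile of the raw trace
    in a centred window of ``baseline_window_s`` seconds; the output is
    (F - F0) / F0.  The running baseline absorbs slow drift by
    construction, and the ratio makes the result invariant to positive
    rescaling of the raw fluorescence.
    """
    if not 0.0 < baseline_percentile < 50.0:
        raise ValueError("baseline_percentile must lie in (0, 50)")
    fs = traces.sampling_rate_hz
    win = int(round(baseline_window_s * fs))
    if win < 10:
        raise ValueError("baseline_window_s must span at least 10 frames")
    if win % 2 == 0:
        win += 1
    if not np.all(np.isfinite(traces.values)):
        raise ValueError("traces contain non-finite values")

    f0 = percentile_filter(
        traces.values, percentile=baseline_percentile, size=(1, win),
        mode="nearest",
    )
    if np.any(f0 <= 0):
        raise ValueError(
            "running baseline is non-positive; input does not look like "
            "raw fluorescence (expected strictly positive values)"
        )
    fluct = (traces.values - f0) / f0
    return TraceMatrix(
        cell_ids=traces.cell_ids, times_s=traces.times_s, values=fluct
    )


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _interp_crossing(t: np.ndarray, x: np.ndarray, i0: int, i1: int,
                     level: float) -> float:
    """Sub-frame crossing time of *level* between frames i0 and i1."""
    x0, x1 = x[i0], x[i1]
    if x1 == x0:
        return float(t[i1])
    frac = (level - x0) / (x1 - x0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t[i0] + frac * (t[i1] - t[i0]))


def _detect_cell(
    t: np.ndarray,
    x_raw: np.ndarray,
    x: np.ndarray,
    seg_level: float,
    peak_level: float,
    min_duration_s: float,
    offset_fraction: float,
) -> list[tuple[float, float, float, float]]:
    """Events for one cell from the smoothed signal *x* (hysteresis).

    Candidate events are contiguous runs above the fixed ``seg_level``;
    a run counts as an event only if its peak exceeds ``peak_level``
    (the k*sigma detection threshold).  Because the segmentation does
    not move with the detection threshold, tightening ``peak_level`` (or
    the duration filter) can only remove events, never split them.
    Boundaries are refined to the crossings of ``offset_fraction * peak``
    (half-height by default) nearest the peak, which makes the measured
    duration insensitive to where the thresholds sit relative to the
    event amplitude.
    """
    above = x > seg_level
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive

    events = []
    for s, e in zip(starts, ends):
        seg = x[s:e]
        p = s + int(np.argmax(seg))
        peak_s = x[p]
        if peak_s <= peak_level:
            continue
        level = max(offset_fraction * peak_s, seg_level)
        level = min(level, peak_s)

        # onset: last upward crossing of `level` before the peak
        i = p
        while i > s and x[i - 1] >= level:
            i -= 1
        if i == 0 or x[i - 1] >= level:
            onset = float(t[i])
        else:
            onset = _interp_crossing(t, x, i - 1, i, level)

        # offset: first downward crossing of `level` after the peak
        j = p
        n = len(x)
        while j < n - 1 and x[j + 1] >= level:
            j += 1
        if j == n - 1 or x[j + 1] >= level:
            offset = float(t[j])
        else:
            offset = _interp_crossing(t, x, j, j + 1, level)

        if offset - onset >= min_duration_s:
            amp = float(np.max(x_raw[s:e]))
            events.append((onset, offset, offset - onset, amp))
    return events


def detect_events(
    fluct: TraceMatrix,
    k_mad: float = 3.0,
    min_duration_s: float = 1.5,
    offset_fraction: float = 0.5,
    smooth_window_s: float = 1.5,
    seg_k: float = 3.0,
    abs_threshold: float | None = None,
) -> pd.DataFrame:
    """Detect calcium oscillations in a fluctuation (dF/F0) matrix.

    Per cell the noise scale is estimated as ``sigma = 1.4826 * MAD`` of
    the (lightly smoothed) fluctuation signal; candidate excursions are
    segmented above ``min(seg_k, k_mad) * sigma`` and accepted as events
    when their peak exceeds ``k_mad * sigma`` (two-threshold hysteresis).
    ``abs_threshold`` replaces both adaptive thresholds when given.
    Event boundaries are measured at ``offset_fraction`` of peak height
    (see :func:`_detect_cell`) and events shorter than ``min_duration_s``
    are discarded.

    Returns a tidy table with columns ``cell_id, onset_s, offset_s,
    duration_s, amplitude``; an empty table (no crossings anywhere) is a
    valid result, not an error.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    fs = fluct.sampling_rate_hz
    if min_duration_s < 2.0 / fs:
        raise ValueError("min_duration_s must span at least 2 frames")
    if not np.all(np.isfinite(fluct.values)):
        raise ValueError("fluctuation matrix contains non-finite values")

    win = max(1, int(round(smooth_window_s * fs)))
    rows: list[tuple] = []
    for row, cell in enumerate(fluct.cell_ids):
        x_raw = fluct.values[row]
        x = uniform_filter1d(x_raw, size=win, mode="nearest") if win > 1 else x_raw
        # centre on the robust baseline of the fluctuation signal: a
        # percentile-based F0 leaves a small positive offset in dF/F0,
        # which must not count toward the threshold
        centre = float(np.median(x))
        x = x - centre
        x_raw = x_raw - centre
        if abs_threshold is not None:
            seg_level = peak_level = abs_threshold
        else:
            sigma = 1.4826 * float(np.median(np.abs(x)))
            if sigma == 0.0:
                continue
            seg_level = min(seg_k, k_mad) * sigma
            peak_level = k_mad * sigma
        for onset, offset, dur, amp in _detect_cell(
            fluct.times_s, x_raw, x, seg_level, peak_level,
            min_duration_s, offset_fraction
        ):
            rows.append((int(cell), onset, offset, dur, amp))

    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def summarize_activity(
    events: pd.DataFrame, n_cells: int, recording_length_s: float
) -> ActivitySummary:
    """The three per-recording activity statistics.

    Active % = 100 x (cells with >= 1 oscillation) / n_cells; frequency =
    mean over *active* cells of oscillations per minute; duration = mean
    over all events.  Frequency and duration are NaN when there are no
    events.
    """
    if recording_length_s <= 0:
        raise ValueError("recording_length_s must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(events) == 0:
        return ActivitySummary(0.0, float("nan"), float("nan"),
                               n_cells, recording_length_s)
    counts = events.groupby("cell_id").size()
    minutes = recording_length_s / 60.0
    return ActivitySummary(
        active_cells_pct=100.0 * len(counts) / n_cells,
        frequency_per_min=float((counts / minutes).mean()),
        mean_duration_s=float(events["duration_s"].mean()),
        n_cells=n_cells,
        recording_length_s=recording_length_s,
    )


# ---------------------------------------------------------------------------
# ROI extraction from image stacks
# ---------------------------------------------------------------------------

def extract_rois(
    stack: np.ndarray,
    expected_radius_um: float,
    pixel_size_um: float,
    sampling_rate_hz: float = 2.0,
):
    """Find somas in a (frames, H, W) stack and extract per-cell traces.

    Somas are local maxima of the temporal-mean image above an Otsu
    threshold, separated by at least one expected radius; each trace is
    the mean intensity inside a disk of ``expected_radius_um`` at the
    detected centroid.  Raises ``ValueError`` when no cells are found.
    """
    from skimage.draw import disk as draw_disk
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu

    from .synthetic import CellMap

    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames, H, W) with >= 2 frames")
    mean_img = stack.mean(axis=0)
    if np.ptp(mean_img) == 0:
        raise ValueError("no cells found")
    thr = threshold_otsu(mean_img)
    r_px = max(1, int(round(expected_radius_um / pixel_size_um)))
    # smooth so each (flat-topped) soma has a single dominant maximum
    from scipy.ndimage import gaussian_filter
    smooth = gaussian_filter(mean_img, sigma=r_px / 2.0)
    peaks = peak_local_max(
        smooth, min_distance=r_px, threshold_abs=thr, exclude_border=False
    )
    if len(peaks) == 0:
        raise ValueError("no cells found")

    # stable ordering: by y then x
    peaks = peaks[np.lexsort((peaks[:, 1], peaks[:, 0]))]
    n_frames, h, w = stack.shape
    traces = np.empty((len(peaks), n_frames))
    for k, (py, px) in enumerate(peaks):
        rr, cc = draw_disk((py, px), r_px, shape=(h, w))
        traces[k] = stack[:, rr, cc].mean(axis=1)

    cell_map = CellMap(
        cell_ids=np.arange(len(peaks), dtype=int),
        x_um=peaks[:, 1].astype(float) * pixel_size_um,
        y_um=peaks[:, 0].astype(float) * pixel_size_um,
        radius_um=np.full(len(peaks), float(expected_radius_um)),
    )
    tm = TraceMatrix(
        cell_ids=np.arange(len(peaks), dtype=int),
        times_s=np.arange(n_frames) / sampling_rate_hz,
        values=traces,
    )
    return cell_map, tm
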