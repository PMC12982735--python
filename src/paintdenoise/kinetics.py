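"""Binding-event time traces: blink linking, dark times, qPAINT.

A cluster's localizations define a binary time trace (frame active or not).
Blinks separated by at most ``max_gap_frames`` dark frames are linked into a
single binding event, compensating for photophysical blinking of the dye
within one hybridization episode. The inter-event dark times of specific
imager-docking binding are exponentially distributed, which downstream
modules exploit both for denoising and for qPAINT molecule counting.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    DarkTimes,
    EventTrain,
    GapScanResult,
    InsufficientEventsError,
    LocalizationTable,
    QpaintEstimate,
    ValidationError,
)


def max_gap_frames_from_seconds(max_gap_s: float, frame_duration_s: float) -> int:
    """Largest whole number of dark frames spanning strictly less than
    ``max_gap_s`` (e.g. a '<1 s' rule at 5 Hz allows 4 dark frames)."""
    if max_gap_s < 0 or frame_duration_s <= 0:
        raise ValidationError("gap and frame duration must be positive")
    return max(0, int(np.floor((max_gap_s - 1e-9) / frame_duration_s)))


def active_frames(table: LocalizationTable, member_indices) -> np.ndarray:
    """Sorted unique frame indices of a cluster (binary trace support).

    Multiple localizations in one frame collapse to a single active frame;
    the exponentiality analysis concerns binding kinetics, not intensity.
    """
    idx = np.asarray(member_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValidationError("cluster has no members")
    return np.unique(table.frame[idx])


def link_events(
    frames: np.ndarray,
    max_gap_frames: int = 0,
    cluster_id: int = -1,
    frame_duration_s: float = 1.0,
) -> EventTrain:
    """Link active frames into binding events, bridging short dark gaps.

    Frames f_i and f_{i+1} join the same event iff the number of intervening
    dark frames (f_{i+1} - f_i - 1) is at most ``max_gap_frames``; events are
    maximal such runs. With gap 0 only consecutive frames link.
    """
    frames = np.asarray(frames, dtype=np.int64)
    if max_gap_frames < 0:
        raise ValidationError("max_gap_frames must be >= 0")
    if frames.size == 0:
        return EventTrain(cluster_id, np.empty((0, 2), np.int64),
                          frame_duration_s, max_gap_frames)
    breaks = np.flatnonzero(np.diff(frames) - 1 > max_gap_frames)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [frames.size - 1]])
    events = np.column_stack([frames[starts], frames[ends]])
    return EventTrain(cluster_id, events, frame_duration_s, max_gap_frames)


def dark_times(
    train: EventTrain,
    convention: str = "gap",
    boundary: str = "none",
    n_frames: Optional[int] = None,
) -> DarkTimes:
    """Inter-event dark times in seconds (length n_events - 1 by default).

    convention "gap": number of dark frames between events times the frame
    duration, floored at one frame; "start_to_start": event start-to-start
    intervals. The gap convention keeps every measured dark time strictly
    above the link-gap threshold used to build the train.

    ``boundary`` optionally appends the acquisition-edge intervals (before
    the first event and/or after the last; "leading" | "trailing" | "both"),
    which needs ``n_frames``. Under docking-strand depletion the trailing
    interval is systematically long, so including it sensitizes the
    exponentiality test to depletion.
    """
    if train.n_events < 2:
        raise InsufficientEventsError(
            f"need >= 2 events for dark times, got {train.n_events}"
        )
    starts = train.events[1:, 0]
    if convention == "gap":
        frames = np.maximum(starts - train.events[:-1, 1] - 1, 1)
    elif convention == "start_to_start":
        frames = starts - train.events[:-1, 0]
    else:
        raise ValidationError(f"unknown dark-time convention {convention!r}")
    frames = frames.astype(np.int64)
    if boundary != "none":
        if boundary not in ("leading", "trailing", "both"):
            raise ValidationError(f"unknown boundary mode {boundary!r}")
        if n_frames is None:
            raise ValidationError("boundary intervals need n_frames")
        extra = []
        if boundary in ("leading", "both"):
            lead = int(train.events[0, 0])
            if lead > 0:
                extra.append(lead)
        if boundary in ("trailing", "both"):
            trail = int(n_frames - 1 - train.events[-1, 1])
            if trail > 0:
                extra.append(trail)
        frames = np.concatenate([frames, np.array(extra, dtype=np.int64)])
    return DarkTimes(frames * train.frame_duration_s)


def fit_exponential(times: DarkTimes | np.ndarray) -> float:
    """Maximum-likelihood exponential mean (= arithmetic mean) in seconds."""
    vals = times.values if isinstance(times, DarkTimes) else np.asarray(times, float)
    if vals.size == 0:
        raise ValidationError("cannot fit an exponential to an empty sample")
    return float(vals.mean())


def cdf_rmse(times: DarkTimes | np.ndarray) -> float:
    """RMSE between the empirical CDF and the fitted exponential CDF.

    Empirical CDF evaluated as i/n at the order statistics; model CDF is
    1 - exp(-x/mean) with the ML mean.
    """
    vals = times.values if isinstance(times, DarkTimes) else np.asarray(times, float)
    if vals.size < 2:
        raise InsufficientEventsError("need >= 2 dark times for a CDF RMSE")
    x = np.sort(vals)
    n = x.size
    emp = np.arange(1, n + 1) / n
    model = 1.0 - np.exp(-x / x.mean())
    return float(np.sqrt(np.mean((emp - model) ** 2)))


def gap_scan(
    frames: np.ndarray,
    gaps_frames: Sequence[int],
    frame_duration_s: float,
    convention: str = "gap",
) -> GapScanResult:
    """CDF RMSE as a function of the link-gap threshold.

    For each candidate gap the trace is re-linked and the exponential fit
    quality recomputed. Gaps yielding fewer than 3 events record NaN. The
    rate is the first difference of the RMSE along the gap grid.
    """
    gaps = np.asarray(list(gaps_frames), dtype=np.int64)
    if gaps.size and np.any(np.diff(gaps) <= 0):
        raise ValidationError("gaps must be sorted strictly ascending")
    rmse = np.full(gaps.size, np.nan)
    for i, g in enumerate(gaps):
        train = link_events(frames, int(g), frame_duration_s=frame_duration_s)
        if train.n_events < 3:
            continue
        rmse[i] = cdf_rmse(dark_times(train, convention))
    return GapScanResult(gaps, rmse, np.diff(rmse))


def qpaint(
    train: EventTrain,
    reference_dark_s: Optional[float] = None,
    convention: str = "gap",
) -> QpaintEstimate:
    """qPAINT quantities: mean dark time and molecule count.

    The relative error of the mean-dark-time estimate from N events is
    1/sqrt(N - 1). With a single-site reference dark time the number of
    binding sites is reference / mean (dark rate scales with site count).
    """
    if train.n_events < 2:
        raise InsufficientEventsError("qPAINT needs >= 2 binding events")
    mean_dark = fit_exponential(dark_times(train, convention))
    rel_err = 1.0 / np.sqrt(train.n_events - 1)
    sites = None if reference_dark_s is None else reference_dark_s / mean_dark
    return QpaintEstimate(mean_dark, train.n_events, rel_err, sites)
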