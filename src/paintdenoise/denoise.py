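"""Cluster classification and region-based threshold selection.

A cluster is kept as specific signal when (a) it has at least ``min_events``
binding events and (b) the Anderson-Darling test does not reject
exponentiality of its inter-event dark times at level ``alpha``. The
optimal ``min_events`` can be read off data by comparing cluster rejection
rates between a signal-dominated region (r_s) and a background-dominated
region or negative control (r_b): the threshold is the smallest value where
the smoothed normalized rate (r_s - r_b)/r_b exceeds a cutoff (default 1).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import exptest, kinetics
from .clustering import labels_from_clusters, two_step_cluster
from .datatypes import (
    Cluster,
    ClusterSummary,
    EventTrain,
    LocalizationTable,
    NormalizedRateSeries,
    RegionMask,
    RejectionCurve,
    ValidationError,
)
from .io import assign_regions


def classify_cluster(
    train: EventTrain,
    min_events: int = 8,
    alpha: float = 0.01,
    min_times: int = 4,
    method: str = "bootstrap",
    B: int = 10_000,
    seed: int = 0,
    convention: str = "gap",
) -> str:
    """Classify one event train: "specific", "noise" or "below_min_events".

    Clusters short of ``min_events`` are rejected outright; otherwise the
    exponentiality test decides. A train that clears the event threshold but
    has too few dark times to test is kept (no evidence against the null);
    with the default min_events = 8 this case cannot arise.
    """
    if train.n_events < min_events:
        return "below_min_events"
    if train.n_events < 2:
        return "specific"
    res = exptest.test_exponentiality(
        kinetics.dark_times(train, convention),
        alpha=alpha,
        min_times=min_times,
        method=method,
        B=B,
        seed=seed,
    )
    return "noise" if res.reject else "specific"


def _train_stats(
    trains: Sequence[EventTrain],
    min_times: int,
    method: str,
    B: int,
    seed: int,
    convention: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-train (n_events, a2, p, mean_dark); p is NaN when untestable."""
    n_events = np.array([t.n_events for t in trains], dtype=np.int64)
    a2 = np.full(len(trains), np.nan)
    p = np.full(len(trains), np.nan)
    mean_dark = np.full(len(trains), np.nan)
    testable = []
    stats = []
    ns = []
    for i, t in enumerate(trains):
        if t.n_events < 2:
            continue
        dt = kinetics.dark_times(t, convention)
        mean_dark[i] = kinetics.fit_exponential(dt)
        if len(dt) < min_times:
            continue
        testable.append(i)
        stats.append(exptest.ad_statistic(dt))
        ns.append(len(dt))
    if testable:
        idx = np.array(testable)
        a2[idx] = stats
        p[idx] = exptest.ad_pvalues(
            np.array(stats), np.array(ns), method=method, B=B, seed=seed
        )
    return n_events, a2, p, mean_dark


def rejection_curve(
    trains: Sequence[EventTrain],
    thresholds: Sequence[int],
    alpha: float = 0.01,
    region: str = "",
    min_times: int = 4,
    method: str = "bootstrap",
    B: int = 10_000,
    seed: int = 0,
    convention: str = "gap",
) -> RejectionCurve:
    """Fraction of clusters rejected as a function of the event threshold.

    Test outcomes are computed once per cluster and reused across
    thresholds; a cluster is rejected at threshold T when it has fewer than
    T events or fails the exponentiality test. The rate is the first
    difference of the fraction, with F(T_min - 1) taken as F(T_min).
    """
    if len(trains) == 0:
        raise ValidationError("need at least one event train")
    thresholds = np.asarray(list(thresholds), dtype=np.int64)
    n_events, _, p, _ = _train_stats(trains, min_times, method, B, seed, convention)
    test_reject = np.where(np.isnan(p), False, p < alpha)
    frac = np.array(
        [np.mean((n_events < T) | test_reject) for T in thresholds]
    )
    rate = np.diff(frac, prepend=frac[0] if frac.size else 0.0)
    return RejectionCurve(thresholds, frac, rate, region)


def smooth(series: np.ndarray, kind: str = "median5") -> np.ndarray:
    """Centered moving median5 / mean3 with truncated windows at the edges.

    NaNs are ignored within each window (all-NaN windows stay NaN); output
    length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    if kind == "median5":
        half = 2
        fn = np.nanmedian
    elif kind == "mean3":
        half = 1
        fn = np.nanmean
    else:
        raise ValidationError(f"unknown smoothing kind {kind!r}")
    out = np.empty_like(x)
    for i in range(x.size):
        win = x[max(0, i - half): i + half + 1]
        out[i] = np.nan if np.all(np.isnan(win)) else fn(win)
    return out


def select_threshold(
    curve_signal: RejectionCurve,
    curve_background: RejectionCurve,
    cutoff: float = 1.0,
    ratio_form: str = "excess",
) -> NormalizedRateSeries:
    """Pick the minimum-events threshold from signal vs background curves.

    Rates are smoothed with a 5-point moving median, the normalized series
    (r_s - r_b)/r_b (or r_s/r_b with ratio_form="ratio") with a 3-point
    moving mean; the threshold is the smallest T whose normalized value
    exceeds ``cutoff``. Where r_b = 0 the series is undefined (NaN) unless
    r_s > 0 there, in which case the limit value +inf applies (signal is
    being rejected while no background remains: always a crossing).
    """
    if not np.array_equal(curve_signal.thresholds, curve_background.thresholds):
        raise ValidationError("signal and background curves use different grids")
    r_s = smooth(curve_signal.rate, "median5")
    r_b = smooth(curve_background.rate, "median5")
    if ratio_form not in ("excess", "ratio"):
        raise ValidationError(f"unknown ratio_form {ratio_form!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        if ratio_form == "excess":
            norm = np.where(r_b > 0, (r_s - r_b) / r_b, np.nan)
        else:
            norm = np.where(r_b > 0, r_s / r_b, np.nan)
    norm[(r_b == 0) & (r_s > 0)] = np.inf
    norm = smooth(norm, "mean3")
    above = np.flatnonzero(np.nan_to_num(norm, nan=-np.inf) > cutoff)
    if above.size:
        return NormalizedRateSeries(
            curve_signal.thresholds, norm,
            int(curve_signal.thresholds[above[0]]), "ok",
        )
    return NormalizedRateSeries(curve_signal.thresholds, norm, None, "no-crossing")


def trains_from_clusters(
    table: LocalizationTable,
    clusters: Sequence[Cluster],
    max_gap_s: float = 1.0,
) -> list[EventTrain]:
    gap = kinetics.max_gap_frames_from_seconds(max_gap_s, table.frame_duration_s)
    return [
        kinetics.link_events(
            kinetics.active_frames(table, c.member_indices),
            gap,
            cluster_id=c.cluster_id,
            frame_duration_s=table.frame_duration_s,
        )
        for c in clusters
    ]


def denoise_table(
    table: LocalizationTable,
    min_events: int = 8,
    alpha: float = 0.01,
    max_gap_s: float = 1.0,
    min_times: int = 4,
    method: str = "bootstrap",
    B: int = 10_000,
    seed: int = 0,
    convention: str = "gap",
    mask: Optional[RegionMask] = None,
    clustering_kwargs: Optional[dict] = None,
) -> tuple[LocalizationTable, list[ClusterSummary]]:
    """Run the full denoising pipeline on a localization table.

    Two-step clustering, blink linking, per-cluster exponentiality testing
    and the minimum-events threshold; the returned table keeps only the
    localizations of clusters classified "specific". Density-noise
    localizations (unclustered by DBSCAN) are dropped: with fewer than 5
    neighbours they cannot carry enough binding events to test.
    """
    clusters = two_step_cluster(table, **(clustering_kwargs or {}))
    trains = trains_from_clusters(table, clusters, max_gap_s)
    n_events, a2, p, mean_dark = _train_stats(
        trains, min_times, method, B, seed, convention
    )
    summaries: list[ClusterSummary] = []
    keep: list[np.ndarray] = []
    for i, (c, t) in enumerate(zip(clusters, trains)):
        if t.n_events < min_events:
            decision = "below_min_events"
        elif not np.isnan(p[i]) and p[i] < alpha:
            decision = "noise"
        else:
            decision = "specific"
        summaries.append(
            ClusterSummary(
                cluster_id=c.cluster_id,
                n_localizations=int(c.member_indices.size),
                n_events=int(n_events[i]),
                centroid_x_nm=c.centroid_nm[0],
                centroid_y_nm=c.centroid_nm[1],
                mean_dark_s=float(mean_dark[i]),
                ad_statistic=float(a2[i]),
                p_value=float(p[i]),
                decision=decision,
            )
        )
        if decision == "specific":
            keep.append(c.member_indices)
    if mask is not None:
        summaries = assign_regions(summaries, mask)
    if keep:
        kept = np.sort(np.concatenate(keep))
    else:
        kept = np.empty(0, dtype=np.int64)
    labels = labels_from_clusters(clusters, len(table))
    filtered = table.with_cluster_id(labels).subset(kept)
    return filtered, summaries


class PaintDenoiser(TransformerMixin, BaseEstimator):
    """scikit-learn-style estimator for kinetics-based cluster filtering.

    ``fit`` runs clustering, trace construction and per-cluster testing on a
    :class:`LocalizationTable` (or DataFrame with the standard columns plus
    acquisition metadata in ``fit`` kwargs); ``transform`` returns the
    filtered table. Deterministic given ``random_state``.

    Attributes
    ----------
    summaries_ : list of :class:`ClusterSummary`
    labels_ : per-localization cluster id (-1 = density noise)
    decisions_ : per-cluster decision strings
    n_specific_ : number of clusters kept
    """

    def __init__(
        self,
        min_events: int = 8,
        alpha: float = 0.01,
        max_gap_s: float = 1.0,
        min_times: int = 4,
        test_method: str = "bootstrap",
        bootstrap_b: int = 10_000,
        dark_time_convention: str = "gap",
        eps_nm: float | str = "auto",
        min_pts: int = 5,
        random_state: int = 0,
    ):
        self.min_events = min_events
        self.alpha = alpha
        self.max_gap_s = max_gap_s
        self.min_times = min_times
        self.test_method = test_method
        self.bootstrap_b = bootstrap_b
        self.dark_time_convention = dark_time_convention
        self.eps_nm = eps_nm
        self.min_pts = min_pts
        self.random_state = random_state

    def _as_table(self, X, **kwargs) -> LocalizationTable:
        if isinstance(X, LocalizationTable):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return LocalizationTable.from_dataframe(
                X,
                frame_duration_s=kwargs.get("frame_duration_s", 1.0),
                n_frames=kwargs.get("n_frames"),
            )
        raise ValidationError("expected a LocalizationTable or DataFrame")

    def fit(self, X, y=None, **kwargs):
        table = self._as_table(X, **kwargs)
        filtered, summaries = denoise_table(
            table,
            min_events=self.min_events,
            alpha=self.alpha,
            max_gap_s=self.max_gap_s,
            min_times=self.min_times,
            method=self.test_method,
            B=self.bootstrap_b,
            seed=self.random_state,
            convention=self.dark_time_convention,
            clustering_kwargs={"eps_nm": self.eps_nm, "min_pts": self.min_pts},
        )
        self.n_localizations_ = len(table)
        self.filtered_ = filtered
        self.summaries_ = summaries
        self.decisions_ = [s.decision for s in summaries]
        self.labels_ = np.full(len(table), -1, dtype=np.int64)
        self.n_specific_ = sum(d == "specific" for d in self.decisions_)
        return self

    def transform(self, X, **kwargs):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "filtered_")
        table = self._as_table(X, **kwargs)
        if len(table) != self.n_localizations_:
            raise ValidationError(
                "transform expects the table the denoiser was fitted on"
            )
        return self.filtered_
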