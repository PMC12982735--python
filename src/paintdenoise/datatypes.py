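"""Core in-memory containers for localization tables, clusters and traces.

Conventions used throughout the package:

* coordinates are continuous, in nanometres, origin at the corner of the
  acquisition field;
* frame indices are 0-based integers; ``frame_duration_s`` converts frame
  counts to seconds;
* a ``cluster_id`` of -1 means "unassigned / density noise".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """A file is missing required structure (e.g. a named column)."""


class InsufficientEventsError(ValidationError):
    """An operation needs more binding events than the cluster has."""


@dataclass
class LocalizationTable:
    """A table of single-molecule localizations plus acquisition metadata.

    One row per detected blink: position (nm), frame index, localization
    precision sigma (nm), optional photon count, optional cluster label.
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    frame: np.ndarray
    precision_nm: np.ndarray
    frame_duration_s: float
    n_frames: int
    photons: Optional[np.ndarray] = None
    cluster_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.precision_nm = np.asarray(self.precision_nm, dtype=float)
        if self.photons is not None:
            self.photons = np.asarray(self.photons, dtype=float)
        if self.cluster_id is not None:
            self.cluster_id = np.asarray(self.cluster_id, dtype=np.int64)

    def __len__(self) -> int:
        return self.x_nm.size

    def validate(self) -> "LocalizationTable":
        n = len(self)
        for name in ("y_nm", "frame", "precision_nm"):
            if getattr(self, name).size != n:
                raise ValidationError(f"column {name!r} length mismatch")
        if self.frame_duration_s <= 0:
            raise ValidationError("frame_duration_s must be > 0")
        if self.n_frames < 0:
            raise ValidationError("n_frames must be >= 0")
        bad = ~(np.isfinite(self.x_nm) & np.isfinite(self.y_nm))
        if bad.any():
            raise ValidationError(
                f"non-finite coordinate at row {int(np.flatnonzero(bad)[0])}"
            )
        bad = ~(np.isfinite(self.precision_nm) & (self.precision_nm > 0))
        if bad.any():
            raise ValidationError(
                f"non-positive precision at row {int(np.flatnonzero(bad)[0])}"
            )
        if n and self.frame.min() < 0:
            raise ValidationError("negative frame index")
        if n and self.frame.max() >= self.n_frames:
            raise ValidationError("frame index >= n_frames")
        return self

    def subset(self, indices: np.ndarray) -> "LocalizationTable":
        """A new table restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        return LocalizationTable(
            x_nm=self.x_nm[idx],
            y_nm=self.y_nm[idx],
            frame=self.frame[idx],
            precision_nm=self.precision_nm[idx],
            frame_duration_s=self.frame_duration_s,
            n_frames=self.n_frames,
            photons=None if self.photons is None else self.photons[idx],
            cluster_id=None if self.cluster_id is None else self.cluster_id[idx],
        )

    def with_cluster_id(self, cluster_id: np.ndarray) -> "LocalizationTable":
        return replace(self, cluster_id=np.asarray(cluster_id, dtype=np.int64))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "x_nm": self.x_nm,
            "y_nm": self.y_nm,
            "frame": self.frame,
            "precision_nm": self.precision_nm,
        }
        if self.photons is not None:
            cols["photons"] = self.photons
        if self.cluster_id is not None:
            cols["cluster_id"] = self.cluster_id
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_duration_s: float,
        n_frames: Optional[int] = None,
    ) -> "LocalizationTable":
        required = ["x_nm", "y_nm", "frame", "precision_nm"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if n_frames is None:
            n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        return cls(
            x_nm=df["x_nm"].to_numpy(dtype=float),
            y_nm=df["y_nm"].to_numpy(dtype=float),
            frame=df["frame"].to_numpy(dtype=np.int64),
            precision_nm=df["precision_nm"].to_numpy(dtype=float),
            frame_duration_s=float(frame_duration_s),
            n_frames=int(n_frames),
            photons=df["photons"].to_numpy(dtype=float) if "photons" in df else None,
            cluster_id=(
                df["cluster_id"].to_numpy(dtype=np.int64)
                if "cluster_id" in df
                else None
            ),
        ).validate()


@dataclass
class RegionMask:
    """Binary raster labelling an image region (e.g. signal vs background).

    Pixel (i, j) covers the half-open square
    ``[origin + j*pixel, origin + (j+1)*pixel) x [origin + i*pixel, ...)``
    with x along columns and y along rows.
    """

    raster: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float]
    label: str

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2 or self.raster.size == 0:
            raise ValidationError("mask raster must be a non-empty 2D array")
        if self.pixel_nm <= 0:
            raise ValidationError("mask pixel_nm must be > 0")

    def label_at(self, x_nm: float, y_nm: float) -> str:
        """Mask label at a point: this mask's label, 'none', or 'outside'."""
        j = int(np.floor((x_nm - self.origin_nm[0]) / self.pixel_nm))
        i = int(np.floor((y_nm - self.origin_nm[1]) / self.pixel_nm))
        ny, nx = self.raster.shape
        if not (0 <= i < ny and 0 <= j < nx):
            return "outside"
        return self.label if self.raster[i, j] else "none"


@dataclass
class RenderedImage:
    """2D histogram rendering of a cluster's localizations."""

    grid: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.pixel_nm <= 0:
            raise ValidationError("pixel_nm must be > 0")
        if (self.grid < 0).any():
            raise ValidationError("rendered grid must be non-negative")


@dataclass
class Cluster:
    """A localization-precision-sized cluster produced by two-step clustering."""

    cluster_id: int
    member_indices: np.ndarray
    centroid_nm: tuple[float, float]
    parent_dbscan_id: int

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        if self.member_indices.size == 0:
            raise ValidationError("cluster must have at least one member")


@dataclass
class EventTrain:
    """Ordered binding events of one cluster after blink linking.

    ``events`` holds inclusive (start_frame, end_frame) intervals.
    """

    cluster_id: int
    events: np.ndarray  # shape (n_events, 2)
    frame_duration_s: float
    max_gap_frames: int = 0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass
class DarkTimes:
    """Inter-event dark times of one cluster, in seconds."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ExpTestResult:
    """Outcome of the Anderson-Darling exponentiality test for one cluster."""

    a2: Optional[float]
    n: int
    p_value: Optional[float]
    alpha: float
    status: str = "ok"  # "ok" | "untestable"

    @property
    def reject(self) -> Optional[bool]:
        if self.status != "ok" or self.p_value is None:
            return None
        return self.p_value < self.alpha


@dataclass
class QpaintEstimate:
    """Molecule-counting quantities derived from a cluster's dark times."""

    mean_dark_s: float
    n_events: int
    relative_error: float
    n_binding_sites: Optional[float] = None


@dataclass
class GapScanResult:
    """RMSE of the exponential CDF fit as a function of the link gap."""

    gaps_frames: np.ndarray
    rmse: np.ndarray
    rmse_rate: np.ndarray


@dataclass
class ClusterSummary:
    """One row of the per-cluster output table."""

    cluster_id: int
    n_localizations: int
    n_events: int
    centroid_x_nm: float
    centroid_y_nm: float
    mean_dark_s: float  # nan when < 2 events
    ad_statistic: float  # nan when untestable
    p_value: float  # nan when untestable
    decision: str  # "specific" | "noise" | "below_min_events"
    region: str = ""


@dataclass
class RejectionCurve:
    """Fraction of rejected clusters vs minimum-events threshold."""

    thresholds: np.ndarray
    fraction_rejected: np.ndarray
    rate: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.int64)
        self.fraction_rejected = np.asarray(self.fraction_rejected, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)


@dataclass
class NormalizedRateSeries:
    """Smoothed (r_s - r_b)/r_b series and the selected threshold."""

    thresholds: np.ndarray
    values: np.ndarray
    selected_threshold: Optional[int]
    status: str = "ok"  # "ok" | "no-crossing"
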