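"""Reading and writing localization tables, region masks and summaries.

CSV tables are comma-separated with a header row; HDF5 tables store one
dataset per column under a single group with acquisition metadata as group
attributes. Column names are configurable through ``column_map`` so tables
exported by other SMLM tools can be ingested without rewriting.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Mapping, Optional, Sequence


import h5py
import pandas as pd

from .datatypes import (
    ClusterSummary,
    FormatError,
    LocalizationTable,
    RegionMask,
    ValidationError,
)

_STANDARD_COLUMNS = ("x_nm", "y_nm", "frame", "precision_nm")
_OPTIONAL_COLUMNS = ("photons", "cluster_id")
_HDF5_GROUP = "localizations"

_SUMMARY_COLUMNS = [f.name for f in dataclasses.fields(ClusterSummary)]


def _infer_dialect(path: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "hdf5"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    ext = os.path.splitext(str(path))[1].lower()
    return "hdf5" if ext in (".h5", ".hdf5", ".hdf") else "csv"


def read_localizations(
    path: str,
    frame_duration_s: float,
    n_frames: Optional[int] = None,
    dialect: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> LocalizationTable:
    """Read a localization table from CSV or HDF5.

    ``column_map`` maps the standard names (x_nm, y_nm, frame, precision_nm,
    photons, cluster_id) to the column names used in the file.
    """
    dialect = _infer_dialect(path, dialect)
    column_map = dict(column_map or {})

    if dialect == "csv":
        df = pd.read_csv(path)
    else:
        cols = {}
        with h5py.File(path, "r") as fh:
            if _HDF5_GROUP not in fh:
                raise FormatError(f"missing HDF5 group {_HDF5_GROUP!r}")
            grp = fh[_HDF5_GROUP]
            for name in grp:
                cols[name] = grp[name][()]
            if n_frames is None and "n_frames" in grp.attrs:
                n_frames = int(grp.attrs["n_frames"])
            if "frame_duration_s" in grp.attrs:
                frame_duration_s = float(grp.attrs["frame_duration_s"])
        df = pd.DataFrame(cols)

    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    for col in _STANDARD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    return LocalizationTable.from_dataframe(df, frame_duration_s, n_frames)


def write_localizations(
    table: LocalizationTable, path: str, dialect: Optional[str] = None
) -> None:
    """Write a localization table as CSV or HDF5 (losslessly re-readable)."""
    table.validate()
    dialect = _infer_dialect(path, dialect)
    df = table.to_dataframe()
    if dialect == "csv":
        df.to_csv(path, index=False)
        return
    with h5py.File(path, "w") as fh:
        grp = fh.create_group(_HDF5_GROUP)
        for col in df.columns:
            grp.create_dataset(col, data=df[col].to_numpy())
        grp.attrs["frame_duration_s"] = table.frame_duration_s
        grp.attrs["n_frames"] = table.n_frames


def read_mask(
    path: str,
    pixel_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    label: str = "signal",
) -> RegionMask:
    """Load a binary mask raster (TIFF/PNG; nonzero = inside the region)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        raster = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raster = iio.imread(path)
    if raster.ndim == 3:  # collapse any colour channels
        raster = raster.max(axis=-1)
    return RegionMask(raster != 0, pixel_nm, origin_nm, label)


def assign_regions(
    summaries: Sequence[ClusterSummary], mask: RegionMask
) -> list[ClusterSummary]:
    """Label each cluster by the mask value at its centroid.

    Centroids on a nonzero mask pixel get the mask's label, those on a zero
    pixel get "none", and those outside the raster get "outside". The input
    is not mutated; assignment is independent of cluster order.
    """
    out = []
    for s in summaries:
        lab = mask.label_at(s.centroid_x_nm, s.centroid_y_nm)
        out.append(dataclasses.replace(s, region=lab))
    return out


def write_cluster_summary(summaries: Iterable[ClusterSummary], path: str) -> None:
    """Write per-cluster summaries as CSV with a stable column order."""
    rows = [dataclasses.asdict(s) for s in summaries]
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_cluster_summary(path: str) -> list[ClusterSummary]:
    df = pd.read_csv(path, keep_default_na=True)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["decision"] = str(d["decision"])
        d["region"] = "" if pd.isna(d.get("region")) else str(d["region"])
        out.append(ClusterSummary(**d))
    return out
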