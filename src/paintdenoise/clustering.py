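"""Two-step clustering of localizations into precision-sized clusters.

DNA-PAINT targets carry one or a few docking strands, so the natural cluster
size is set by the localization precision sigma (radius ~ 2 sigma). Density
clustering (DBSCAN) alone merges neighbouring targets in dense areas; the
second step breaks each DBSCAN cluster into precision-sized sub-clusters by
k-means, seeded from peaks of the cross-correlation between a rendered
cluster image and a 2D Gaussian template of width sigma.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .datatypes import (
    Cluster,
    LocalizationTable,
    RenderedImage,
    ValidationError,
)


def median_precision(table: LocalizationTable) -> float:
    """Median localization precision (nm); lower-of-two-middles when even.

    The lower-middle convention makes the result an actually observed
    precision value for any sample size.
    """
    if len(table) == 0:
        raise ValidationError("cannot take median precision of an empty table")
    vals = np.sort(table.precision_nm)
    return float(vals[(vals.size - 1) // 2])


def dbscan_cluster(
    table: LocalizationTable, eps_nm: float, min_pts: int = 5
) -> np.ndarray:
    """DBSCAN on (x, y) with Euclidean distance; -1 marks density noise.

    A core point has >= min_pts neighbours within eps (itself included).
    Border points reachable from several clusters go to the cluster that is
    discovered first in record-scan order (deterministic).
    """
    if len(table) == 0:
        raise ValidationError("cannot cluster an empty table")
    if eps_nm <= 0 or min_pts < 1:
        raise ValidationError("eps_nm must be > 0 and min_pts >= 1")
    xy = np.column_stack([table.x_nm, table.y_nm])
    return DBSCAN(eps=eps_nm, min_samples=min_pts).fit_predict(xy)


def render_cluster(
    table: LocalizationTable,
    member_indices: np.ndarray,
    pixel_nm: float,
    pad_nm: Optional[float] = None,
    gaussian_render: bool = False,
) -> RenderedImage:
    """2D histogram of member positions, padded so template peaks fit.

    The grid is padded by >= 3x the members' median precision on every side
    (overridable via ``pad_nm``); the sum over the grid equals the number of
    members. With ``gaussian_render`` each localization is blurred by its
    precision instead of binned as a point mass (off by default: the
    template correlation supplies the smoothing).
    """
    idx = np.asarray(member_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValidationError("cannot render an empty cluster")
    if pixel_nm <= 0:
        raise ValidationError("pixel_nm must be > 0")
    x = table.x_nm[idx]
    y = table.y_nm[idx]
    prec = np.sort(table.precision_nm[idx])
    med = float(prec[(prec.size - 1) // 2])
    pad = 3.0 * med if pad_nm is None else float(pad_nm)
    x0 = x.min() - pad
    y0 = y.min() - pad
    nx = max(1, int(np.ceil((x.max() + pad - x0) / pixel_nm)))
    ny = max(1, int(np.ceil((y.max() + pad - y0) / pixel_nm)))
    grid, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((y0, y0 + ny * pixel_nm), (x0, x0 + nx * pixel_nm))
    )
    if gaussian_render:
        grid = ndimage.gaussian_filter(grid, sigma=med / pixel_nm, mode="constant")
        grid *= idx.size / max(grid.sum(), np.finfo(float).tiny)
    return RenderedImage(grid=grid, pixel_nm=pixel_nm, origin_nm=(x0, y0))


def seed_centroids(
    image: RenderedImage,
    sigma_nm: float,
    rel_threshold: float = 0.3,
    min_sep_nm: Optional[float] = None,
) -> np.ndarray:
    """Seed positions (nm) from Gaussian-template cross-correlation peaks.

    The rendered image is correlated with a unit-sum 2D Gaussian of width
    ``sigma_nm``; seeds are the local maxima of the correlation map above
    ``rel_threshold`` times its global maximum, thinned so that surviving
    peaks are separated by at least ``min_sep_nm`` (default: sigma_nm).
    The global maximum is always a seed.
    """
    if sigma_nm <= 0:
        raise ValidationError("sigma_nm must be > 0")
    if min_sep_nm is None:
        min_sep_nm = sigma_nm
    grid = image.grid
    if grid.max() <= 0:
        raise ValidationError("cannot seed from an all-zero image")
    sigma_px = sigma_nm / image.pixel_nm
    corr = ndimage.gaussian_filter(grid, sigma=sigma_px, mode="constant")
    cmax = corr.max()
    local_max = corr == ndimage.maximum_filter(corr, size=3, mode="constant")
    cand = local_max & (corr >= rel_threshold * cmax)
    rows, cols = np.nonzero(cand)
    # strongest-first greedy thinning with the minimum-separation rule
    order = np.argsort(corr[rows, cols])[::-1]
    rows, cols = rows[order], cols[order]
    px = image.pixel_nm
    xs = image.origin_nm[0] + (cols + 0.5) * px
    ys = image.origin_nm[1] + (rows + 0.5) * px
    keep_x: list[float] = []
    keep_y: list[float] = []
    for x, y in zip(xs, ys):
        if all((x - kx) ** 2 + (y - ky) ** 2 >= min_sep_nm**2
               for kx, ky in zip(keep_x, keep_y)):
            keep_x.append(float(x))
            keep_y.append(float(y))
    return np.column_stack([keep_x, keep_y])


def kmeans_partition(
    table: LocalizationTable,
    member_indices: np.ndarray,
    seeds: np.ndarray,
    parent_dbscan_id: int = 0,
    first_cluster_id: int = 0,
    tol_nm: float = 0.01,
    max_iter: int = 300,
) -> list[Cluster]:
    """Lloyd's k-means on member positions, initialized exactly at ``seeds``.

    Deterministic: no random restarts, nearest-centroid ties break toward
    the lowest seed index, convergence when the largest centroid shift drops
    below ``tol_nm``. If there are fewer members than seeds, k is reduced to
    the member count. Empty sub-clusters are dropped from the result.
    """
    idx = np.asarray(member_indices, dtype=np.int64)
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    if seeds.shape[0] < 1:
        raise ValidationError("need at least one seed")
    pts = np.column_stack([table.x_nm[idx], table.y_nm[idx]])
    k = min(seeds.shape[0], pts.shape[0])
    centers = seeds[:k].copy()
    labels = np.zeros(pts.shape[0], dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        shift = 0.0
        for j in range(k):
            sel = labels == j
            if sel.any():
                new = pts[sel].mean(axis=0)
                shift = max(shift, float(np.hypot(*(new - centers[j]))))
                centers[j] = new
        if shift < tol_nm:
            break
    out: list[Cluster] = []
    cid = first_cluster_id
    for j in range(k):
        sel = labels == j
        if not sel.any():
            continue
        members = idx[sel]
        centroid = (
            float(table.x_nm[members].mean()),
            float(table.y_nm[members].mean()),
        )
        out.append(Cluster(cid, members, centroid, parent_dbscan_id))
        cid += 1
    return out


def two_step_cluster(
    table: LocalizationTable,
    eps_nm: float | str = "auto",
    min_pts: int = 5,
    render_pixel_frac: float = 0.5,
    peak_rel_threshold: float = 0.3,
    peak_min_sep_frac: float = 1.0,
    gaussian_render: bool = False,
) -> list[Cluster]:
    """DBSCAN followed by template-seeded k-means on every DBSCAN cluster.

    Defaults follow the recommended protocol: eps = median localization
    precision, min_pts = 5, render pixel = precision/2, template sigma =
    precision. Density-noise localizations stay unassigned.
    """
    if len(table) == 0:
        return []
    med = median_precision(table)
    eps = med if eps_nm == "auto" else float(eps_nm)
    labels = dbscan_cluster(table, eps, min_pts)
    clusters: list[Cluster] = []
    pixel = med * render_pixel_frac
    for db_id in np.unique(labels[labels >= 0]):
        members = np.flatnonzero(labels == db_id)
        img = render_cluster(table, members, pixel, gaussian_render=gaussian_render)
        seeds = seed_centroids(
            img,
            sigma_nm=med,
            rel_threshold=peak_rel_threshold,
            min_sep_nm=med * peak_min_sep_frac,
        )
        clusters.extend(
            kmeans_partition(
                table,
                members,
                seeds,
                parent_dbscan_id=int(db_id),
                first_cluster_id=len(clusters),
            )
        )
    return clusters


def labels_from_clusters(clusters: Sequence[Cluster], n: int) -> np.ndarray:
    """Per-localization cluster id array (-1 = unassigned)."""
    labels = np.full(n, -1, dtype=np.int64)
    for c in clusters:
        labels[c.member_indices] = c.cluster_id
    return labels


class TwoStepClusterer(ClusterMixin, BaseEstimator):
    """scikit-learn-style front end for the two-step clustering.

    Parameters mirror :func:`two_step_cluster`. ``fit`` accepts a
    :class:`LocalizationTable`, a DataFrame with the standard columns, or an
    (n, 3) array of (x_nm, y_nm, precision_nm); with an (n, 2) array a
    numeric ``eps_nm`` doubles as the precision scale.

    Attributes
    ----------
    labels_ : per-localization cluster id, -1 for density noise
    clusters_ : list of :class:`Cluster`
    median_precision_ : precision scale used for eps / template sigma
    """

    def __init__(
        self,
        eps_nm: float | str = "auto",
        min_pts: int = 5,
        render_pixel_frac: float = 0.5,
        peak_rel_threshold: float = 0.3,
        peak_min_sep_frac: float = 1.0,
        gaussian_render: bool = False,
    ):
        self.eps_nm = eps_nm
        self.min_pts = min_pts
        self.render_pixel_frac = render_pixel_frac
        self.peak_rel_threshold = peak_rel_threshold
        self.peak_min_sep_frac = peak_min_sep_frac
        self.gaussian_render = gaussian_render

    def _as_table(self, X) -> LocalizationTable:
        if isinstance(X, LocalizationTable):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return LocalizationTable.from_dataframe(X, frame_duration_s=1.0)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (2, 3):
            raise ValidationError("expected an (n, 2) or (n, 3) array")
        if X.shape[1] == 3:
            prec = X[:, 2]
        else:
            if self.eps_nm == "auto":
                raise ValidationError(
                    "(n, 2) input needs a numeric eps_nm to set the scale"
                )
            prec = np.full(X.shape[0], float(self.eps_nm))
        return LocalizationTable(
            x_nm=X[:, 0],
            y_nm=X[:, 1],
            frame=np.zeros(X.shape[0], dtype=np.int64),
            precision_nm=prec,
            frame_duration_s=1.0,
            n_frames=1,
        )

    def fit(self, X, y=None):
        table = self._as_table(X)
        self.median_precision_ = median_precision(table) if len(table) else np.nan
        self.clusters_ = two_step_cluster(
            table,
            eps_nm=self.eps_nm,
            min_pts=self.min_pts,
            render_pixel_frac=self.render_pixel_frac,
            peak_rel_threshold=self.peak_rel_threshold,
            peak_min_sep_frac=self.peak_min_sep_frac,
            gaussian_render=self.gaussian_render,
        )
        self.labels_ = labels_from_clusters(self.clusters_, len(table))
        self.n_clusters_ = len(self.clusters_)
        return self
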