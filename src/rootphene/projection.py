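"""Rotational 2D projection series and per-metric projection variability.

A 3D root system is rotated about the vertical axis in fixed steps
(default 20 degrees, 18 views), each view is orthographically projected
onto the x-y image plane (depth is preserved exactly), 2D analogs of the
aggregate metrics are computed per view, and each metric's mean and
coefficient of variation across views quantify how sensitive the metric is
to the imaging plane.  In 2D, "convex hull volume" means the area of the
2D hull and "convex hull area" its perimeter; solidity uses a projected
silhouette-area proxy (projected length x mean diameter over hull area)
because projected volume is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .metrics import (AggregateMetrics, DepthProfile, count_stats,
                      densify_segments, fractal_box_count,
                      min_enclosing_ellipse_2d, DEFAULT_SLICES, BOX_S_MIN)
from .simulate import RootSystem

#: metric names reported per view (ellipses exist only in 2D)
PROJECTED_METRICS = AggregateMetrics.METRIC_NAMES + ("angle",)


@dataclass
class Projection2D:
    """One 2D view: projected polylines with radii and root grouping."""

    azimuth: float
    starts: np.ndarray        # (n, 2) segment starts (x, depth)
    ends: np.ndarray          # (n, 2)
    radii: np.ndarray
    polylines: list           # (class_id, (k, 2) vertex array) per root
    species: str
    day: float

    def endpoints(self) -> np.ndarray:
        return np.vstack([pl for _, pl in self.polylines])


def rotate_project(system: RootSystem, azimuth: float) -> Projection2D:
    """Rotate about the vertical axis by ``azimuth`` degrees and project
    onto the x-y plane.  Depth (y) is preserved exactly."""
    rot = system.rotated(azimuth)
    starts, ends, radii = rot.segment_arrays()
    polylines = [(r.class_id, np.asarray(r.points, dtype=float)[:, :2])
                 for r in rot.roots]
    return Projection2D(azimuth=azimuth, starts=starts[:, :2],
                        ends=ends[:, :2], radii=radii, polylines=polylines,
                        species=system.species, day=system.day)


def _apparent_angle(poly: np.ndarray, arc: float = 5.0) -> float:
    """Chord angle from horizontal at 5 cm arc along a projected polyline."""
    seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        return 0.0
    if total < arc:
        p = poly[-1]
    else:
        i = int(np.searchsorted(cum, arc))
        t = (arc - cum[i - 1]) / max(seglen[i - 1], 1e-15)
        p = poly[i - 1] + t * (poly[i] - poly[i - 1])
    dy = p[1] - poly[0][1]
    dh = abs(p[0] - poly[0][0])
    if dh < 1e-12 and abs(dy) < 1e-12:
        return 0.0
    return min(90.0, max(0.0, math.degrees(math.atan2(dy, dh))))


def metrics_2d(proj: Projection2D, n_slices: int = DEFAULT_SLICES,
               s_min: float = BOX_S_MIN) -> AggregateMetrics:
    """2D analogs of the aggregate metrics for one projected view."""
    lengths = np.linalg.norm(proj.ends - proj.starts, axis=1)
    if len(lengths) == 0:
        raise ValueError("empty projection")
    m = AggregateMetrics()
    m.total_length = float(lengths.sum())
    m.total_area = float(np.sum(2.0 * np.pi * proj.radii * lengths))
    m.total_volume = float(np.sum(np.pi * proj.radii ** 2 * lengths))
    pts = proj.endpoints()
    if len(np.unique(np.round(pts, 12), axis=0)) < 2:
        m.flags["degenerate"] = "single-point projection"
        return m
    m.max_width = float(pts[:, 0].max() - pts[:, 0].min())
    m.max_depth = float(pts[:, 1].max())

    # depth-slice counts on projected segments
    if m.max_depth > 0:
        depths = m.max_depth * (2 * np.arange(n_slices) + 1) / (2 * n_slices)
        from .metrics import _straddle_counts
        counts = _straddle_counts(proj.starts[:, 1], proj.ends[:, 1], depths)
        prof = DepthProfile(depths=depths, counts=counts)
        ylo = np.minimum(proj.starts[:, 1], proj.ends[:, 1])
        yhi = np.maximum(proj.starts[:, 1], proj.ends[:, 1])
        m.median_root_count, m.max_root_count, m.bushiness = count_stats(prof)
        # volume distribution with projected lengths
        plane = m.max_depth / 3.0
        vols = np.pi * proj.radii ** 2 * lengths
        span = yhi - ylo
        with np.errstate(divide="ignore", invalid="ignore"):
            fa_ = np.clip((plane - ylo) / span, 0.0, 1.0)
        fa_[span <= 1e-15] = (ylo[span <= 1e-15] <= plane)
        v_above = float(np.sum(vols * fa_))
        v_below = float(np.sum(vols * (1 - fa_)))
        m.volume_distribution = v_above / v_below if v_below > 0 \
            else float("inf")

    try:
        hull = ConvexHull(pts)
        m.convex_hull_volume = float(hull.volume)  # 2D hull area
        m.convex_hull_area = float(hull.area)      # 2D hull perimeter
        mean_diam = float(np.mean(2.0 * proj.radii))
        m.solidity = (m.total_length * mean_diam) / m.convex_hull_volume
        m.flags["solidity"] = "projected-silhouette proxy"
    except QhullError:
        m.flags["convex_hull"] = "degenerate projection"

    m.ellipse_major, m.ellipse_minor, m.ellipse_aspect = \
        min_enclosing_ellipse_2d(pts)
    if not np.isfinite(m.ellipse_aspect):
        m.flags["ellipse"] = "degenerate (collinear projection)"

    dense = densify_segments(proj.starts, proj.ends, s_min / 2.0)
    m.fd, m.fa, reliable = fractal_box_count(dense, dim=2, s_min=s_min)
    if not reliable:
        m.flags["fractal"] = "fewer than 3 usable box sizes"
    return m


@dataclass
class ProjectionSeries:
    """All views of one phenotype with per-view metrics, means and CVs."""

    angles: list[float]
    views: list[AggregateMetrics]
    angle_by_view: list[float]          # mean apparent axial angle per view
    table: pd.DataFrame = field(default=None)  # view x metric
    mean: pd.Series = field(default=None)
    cv: pd.Series = field(default=None)


def series(system: RootSystem, step: float = 20.0,
           n_slices: int = DEFAULT_SLICES,
           s_min: float = BOX_S_MIN) -> ProjectionSeries:
    """Compute the full rotational series and per-metric mean and CV.

    CV uses the sample standard deviation (ddof=1) over views divided by
    the mean; metrics that are NaN/inf in any view propagate NaN.
    """
    if step <= 0 or (360.0 / step) != int(360.0 / step):
        raise ValueError("step must divide 360")
    angles = [step * i for i in range(int(360.0 / step))]
    views, appangles = [], []
    for az in angles:
        proj = rotate_project(system, az)
        views.append(metrics_2d(proj, n_slices=n_slices, s_min=s_min))
        axial = [_apparent_angle(pl) for cid, pl in proj.polylines
                 if cid != "lateral"]
        appangles.append(float(np.mean(axial)) if axial else float("nan"))
    rows = []
    for v, ang in zip(views, appangles):
        d = v.to_dict()
        d["angle"] = ang
        rows.append(d)
    table = pd.DataFrame(rows, index=angles)
    table.replace([np.inf, -np.inf], np.nan, inplace=True)
    mean = table.mean()
    sd = table.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    return ProjectionSeries(angles=angles, views=views,
                            angle_by_view=appangles, table=table,
                            mean=mean, cv=cv)


def cv_report(series_list: list[ProjectionSeries],
              ids: list | None = None) -> pd.DataFrame:
    """Long-format phenotype x metric x cv table."""
    records = []
    if ids is None:
        ids = list(range(len(series_list)))
    for pid, s in zip(ids, series_list):
        for metric, cv in s.cv.items():
            records.append({"phenotype": pid, "metric": metric,
                            "cv": cv, "mean": s.mean[metric]})
    return pd.DataFrame(records,
                        columns=["phenotype", "metric", "cv", "mean"])
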