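"""The 17 aggregate root-architecture metrics.

Size metrics (total length / surface area / volume), extent metrics
(maximum depth, maximum width by exact minimum enclosing circle), root-count
statistics over horizontal depth slices (median count, 84th-percentile
count, bushiness index), volume distribution (above / below one-third
depth), convex hull volume and surface area, solidity, minimum enclosing
ellipse axes (2D only, averaged over rotational projections), and
box-counting fractal dimension (FD) and fractal abundance (FA).

Degenerate geometry (coplanar hulls, zero depth, empty slices) yields
flagged NaN/inf values rather than exceptions so that batch runs over
thousands of phenotypes never abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely import MultiPoint
from shapely import minimum_bounding_radius

from .simulate import RootSystem

BOX_S_MIN = 2e-1   # cm; smallest box edge in the halving series
DEFAULT_SLICES = 50


@dataclass
class AggregateMetrics:
    total_length: float = np.nan      # cm
    total_area: float = np.nan        # cm^2
    total_volume: float = np.nan      # cm^3
    max_width: float = np.nan         # cm
    max_depth: float = np.nan         # cm
    median_root_count: float = np.nan
    max_root_count: float = np.nan    # 84th-percentile count
    bushiness: float = np.nan
    volume_distribution: float = np.nan
    convex_hull_volume: float = np.nan  # cm^3 (3D) or hull area cm^2 (2D)
    convex_hull_area: float = np.nan    # cm^2 (3D) or hull perimeter cm (2D)
    solidity: float = np.nan
    ellipse_major: float = np.nan     # cm (projection mean in 3D studies)
    ellipse_minor: float = np.nan     # cm
    ellipse_aspect: float = np.nan
    fd: float = np.nan
    fa: float = np.nan                # log10 box count at 1 cm boxes
    flags: dict = field(default_factory=dict)

    METRIC_NAMES = (
        "total_length", "total_area", "total_volume", "max_width",
        "max_depth", "median_root_count", "max_root_count", "bushiness",
        "volume_distribution", "convex_hull_volume", "convex_hull_area",
        "solidity", "ellipse_major", "ellipse_minor", "ellipse_aspect",
        "fd", "fa",
    )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "flags"}


@dataclass
class DepthProfile:
    depths: np.ndarray   # slice-plane depths, cm
    counts: np.ndarray   # segments straddling each plane


# ---------------------------------------------------------------------------
# size and extent
# ---------------------------------------------------------------------------

def totals(system: RootSystem) -> tuple[float, float, float]:
    """Summed segment length, lateral surface area and cylinder volume."""
    starts, ends, radii = system.segment_arrays()
    if len(starts) == 0:
        raise ValueError("empty root system")
    lengths = np.linalg.norm(ends - starts, axis=1)
    area = float(np.sum(2.0 * np.pi * radii * lengths))
    volume = float(np.sum(np.pi * radii ** 2 * lengths))
    return float(lengths.sum()), area, volume


def max_depth(system: RootSystem) -> float:
    return float(system.endpoints()[:, 1].max())


def max_width(system: RootSystem) -> float:
    """Diameter of the exact minimum enclosing circle of all endpoints
    projected to the horizontal (x, z) plane."""
    pts = system.endpoints()[:, [0, 2]]
    uniq = np.unique(np.round(pts, 12), axis=0)
    if len(uniq) == 1:
        return 0.0
    return 2.0 * float(minimum_bounding_radius(MultiPoint(uniq)))


# ---------------------------------------------------------------------------
# depth-slice root counts
# ---------------------------------------------------------------------------

def depth_profile(system: RootSystem,
                  n_slices: int = DEFAULT_SLICES) -> DepthProfile:
    """Segments crossing horizontal planes at evenly spaced depths.

    Planes sit at the midpoints of ``n_slices`` equal depth bins spanning
    (0, max_depth).  A segment covers the half-open depth interval
    [min(y), max(y)) so a plane coinciding with a shared polyline vertex is
    crossed once, not twice.  A zero-depth (surface-bound) system
    degenerates to a single plane counting the roots at the surface.
    """
    starts, ends, _ = system.segment_arrays()
    md = max_depth(system)
    if md <= 0:
        return DepthProfile(depths=np.array([0.0]),
                            counts=np.array([len(system.roots)]))
    depths = md * (2 * np.arange(n_slices) + 1) / (2 * n_slices)
    counts = _straddle_counts(starts[:, 1], ends[:, 1], depths)
    return DepthProfile(depths=depths, counts=counts)


def _straddle_counts(y0: np.ndarray, y1: np.ndarray,
                     depths: np.ndarray) -> np.ndarray:
    ylo = np.minimum(y0, y1)
    yhi = np.maximum(y0, y1)
    deepest = yhi.max()
    cover = (ylo[None, :] <= depths[:, None]) & \
            (yhi[None, :] > depths[:, None])
    # keep the tip segment countable at a plane through the deepest point
    cover |= (yhi[None, :] == depths[:, None]) & (yhi[None, :] == deepest)
    return np.count_nonzero(cover, axis=1)


def count_stats(profile: DepthProfile) -> tuple[float, float, float]:
    """(median count, 84th-percentile count, bushiness index).

    Median uses the midpoint rule; the 84th percentile is nearest-rank on
    the sorted counts; bushiness = 84th-percentile / median (NaN when the
    median is 0).
    """
    counts = np.asarray(profile.counts)
    if counts.size == 0:
        raise ValueError("empty depth profile")
    med = float(np.median(counts))
    srt = np.sort(counts)
    rank = max(1, math.ceil(0.84 * counts.size))
    p84 = float(srt[rank - 1])
    bush = p84 / med if med > 0 else float("nan")
    return med, p84, bush


# ---------------------------------------------------------------------------
# volume distribution
# ---------------------------------------------------------------------------

def volume_distribution(system: RootSystem) -> float:
    """Root volume above one-third of maximum depth over volume below it.

    Segments crossing the plane are split exactly, allocating cylinder
    volume by length fraction.  All-above-plane systems return +inf
    (flagged downstream).
    """
    starts, ends, radii = system.segment_arrays()
    md = max_depth(system)
    if md <= 0:
        raise ValueError("zero-depth system")
    plane = md / 3.0
    lengths = np.linalg.norm(ends - starts, axis=1)
    vols = np.pi * radii ** 2 * lengths
    ylo = np.minimum(starts[:, 1], ends[:, 1])
    yhi = np.maximum(starts[:, 1], ends[:, 1])
    span = yhi - ylo
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_above = np.clip((plane - ylo) / span, 0.0, 1.0)
    frac_above[span <= 1e-15] = (ylo[span <= 1e-15] <= plane)
    v_above = float(np.sum(vols * frac_above))
    v_below = float(np.sum(vols * (1.0 - frac_above)))
    if v_below <= 0:
        return float("inf")
    return v_above / v_below


# ---------------------------------------------------------------------------
# convex hull and solidity
# ---------------------------------------------------------------------------

def convex_hull_3d(system: RootSystem) -> tuple[float, float, bool]:
    """(hull volume, hull surface area, degenerate flag).

    Hull of the segment endpoints (the hull of a polyline equals the hull
    of its vertices).  Coplanar/collinear systems return volume 0 with the
    planar hull area where defined, flagged degenerate.
    """
    pts = system.endpoints()
    try:
        hull = ConvexHull(pts)
        return float(hull.volume), float(hull.area), False
    except QhullError:
        area = _planar_hull_area(pts)
        return 0.0, area, True


def _planar_hull_area(pts: np.ndarray) -> float:
    """Area of the 2D hull of a (near-)coplanar 3D point set; 0 if
    collinear."""
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    if len(s) < 2 or s[1] < 1e-12:
        return 0.0
    proj = (pts - c) @ vt[:2].T
    try:
        return float(ConvexHull(proj).volume)  # 2D: .volume is the area
    except QhullError:
        return 0.0


def solidity(system: RootSystem) -> float:
    _, _, vol = totals(system)
    hv, _, degen = convex_hull_3d(system)
    if degen or hv <= 0:
        return float("nan")
    return vol / hv


# ---------------------------------------------------------------------------
# minimum enclosing ellipse (2D projections only)
# ---------------------------------------------------------------------------

def min_enclosing_ellipse_2d(points: np.ndarray, tol: float = 1e-7,
                             max_iter: int = 2000, return_form: bool = False):
    """Minimum-area enclosing ellipse of a 2D point set (Khachiyan).

    Returns (major_axis_length, minor_axis_length, aspect_ratio) with full
    axis lengths (2a >= 2b) and aspect = major/minor.  Degenerate sets
    (identical or collinear points) return the extent as major axis, minor
    axis 0 and aspect inf.  With ``return_form`` the ellipse's center and
    shape matrix A ((x-c)' A (x-c) <= 1) are appended to the tuple.
    """
    P = np.unique(np.asarray(points, dtype=float), axis=0)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(P) == 1:
        if return_form:
            return 0.0, 0.0, float("nan"), P[0], None
        return 0.0, 0.0, float("nan")
    # rank check: collinear -> degenerate
    c0 = P.mean(axis=0)
    s = np.linalg.svd(P - c0, compute_uv=False)
    if s[1] < 1e-10 * max(1.0, s[0]):
        d = np.linalg.norm(P - c0, axis=1)
        if return_form:
            return float(2.0 * d.max()), 0.0, float("inf"), c0, None
        return float(2.0 * d.max()), 0.0, float("inf")
    # the enclosing ellipse depends only on the convex hull vertices
    if len(P) > 16:
        try:
            P = P[ConvexHull(P).vertices]
        except QhullError:
            pass
    n = len(P)
    Q = np.column_stack([P, np.ones(n)]).T  # 3 x n
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        if M[j] / 3.0 - 1.0 <= tol:  # all points inside to tolerance
            break
        step = (M[j] - 3.0) / (3.0 * (M[j] - 1.0))
        u = (1.0 - step) * u
        u[j] += step
    center = P.T @ u
    cov = ((P.T * u) @ P) - np.outer(center, center)
    A = np.linalg.inv(cov) / 2.0  # (x-c)' A (x-c) <= 1
    # exact-containment correction: inflate to the farthest support point
    # (q is convex, so its maximum over the hull is attained at a vertex)
    q = np.einsum("ni,ij,nj->n", P - center, A, P - center)
    A = A / q.max()
    evals = np.linalg.eigvalsh(A)
    semi = 1.0 / np.sqrt(evals)   # descending semi-axes
    major, minor = 2.0 * semi.max(), 2.0 * semi.min()
    if return_form:
        return (float(major), float(minor), float(major / minor),
                center, A)
    return float(major), float(minor), float(major / minor)


# ---------------------------------------------------------------------------
# box-counting fractal dimension and abundance
# ---------------------------------------------------------------------------

def densify_segments(starts: np.ndarray, ends: np.ndarray,
                     spacing: float) -> np.ndarray:
    """Sample points along segments at most ``spacing`` apart (inclusive of
    both endpoints), for resolution-independent box counting."""
    lengths = np.linalg.norm(ends - starts, axis=1)
    nsub = np.maximum(1, np.ceil(lengths / spacing).astype(int))
    pts = []
    for n in np.unique(nsub):  # vectorize per subdivision count
        mask = nsub == n
        t = np.linspace(0.0, 1.0, n + 1)
        block = (starts[mask][:, None, :] +
                 t[None, :, None] * (ends[mask] - starts[mask])[:, None, :])
        pts.append(block.reshape(-1, starts.shape[1]))
    return np.vstack(pts)


def canonical_horizontal(pts: np.ndarray) -> np.ndarray:
    """Rotate a 3D point cloud about the vertical axis into a canonical
    frame: the principal horizontal axis is aligned with x, with signs
    fixed by the farthest-point direction.

    Box counting on the canonical cloud is invariant under rotations of
    the original system about the vertical axis, making 3D FD/FA a
    property of the architecture rather than of the imaging frame.
    """
    pts = np.asarray(pts, dtype=float)
    h = pts[:, [0, 2]]
    c = h.mean(axis=0)
    hc = h - c
    cov = hc.T @ hc
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    # deterministic sign: farthest point projects positively
    far = hc[int(np.argmax(np.linalg.norm(hc, axis=1)))]
    if far @ major < 0:
        major = -major
    minor = np.array([-major[1], major[0]])  # right-handed
    out = pts.copy()
    out[:, 0] = hc @ major
    out[:, 2] = hc @ minor
    return out


def box_count(points: np.ndarray, s_min: float = BOX_S_MIN):
    """Occupied-box counts N(s) over a halving series of box edges.

    The series starts at the bounding-cube edge and halves while s >= s_min;
    grids are anchored at the bounding-box minimum corner.  Returns
    (sizes, counts).
    """
    pts = np.asarray(points, dtype=float)
    mins = pts.min(axis=0)
    span = float((pts.max(axis=0) - mins).max())
    if span <= 0:
        return np.array([]), np.array([])
    sizes, counts = [], []
    s = span
    d = pts.shape[1]
    while s >= s_min - 1e-12:
        idx = np.floor((pts - mins) / s).astype(np.int64)
        top = max(1, math.ceil(span / s - 1e-9))
        np.clip(idx, 0, top - 1, out=idx)
        key = idx[:, 0]
        for k in range(1, d):  # pack grid indices into one integer key
            key = key * top + idx[:, k]
        counts.append(len(np.unique(key)))
        sizes.append(s)
        s /= 2.0
    return np.asarray(sizes), np.asarray(counts, dtype=float)


def fractal_box_count(system_or_points, dim: int = 3,
                      s_min: float = BOX_S_MIN):
    """Box-counting fractal dimension and abundance.

    FD is the least-squares slope of log10 N(s) against log10(1/s); FA is
    the intercept, i.e. log10 of the extrapolated box count at s = 1 cm.
    Returns (fd, fa, reliable); ``reliable`` is False when fewer than three
    box sizes are usable (the values are still returned).  A single point
    has FD = FA = 0 exactly.
    """
    if isinstance(system_or_points, RootSystem):
        starts, ends, _ = system_or_points.segment_arrays()
        pts = densify_segments(starts, ends, s_min / 2.0)
        if dim == 2:
            pts = pts[:, :2]
        else:
            pts = canonical_horizontal(pts)
    else:
        pts = np.asarray(system_or_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != dim:
        raise ValueError(f"points must be (n, {dim})")
    sizes, counts = box_count(pts, s_min=s_min)
    if sizes.size == 0:  # all points coincide
        return 0.0, 0.0, False
    if sizes.size < 3:
        # too few scales for a fit; report the single/two-scale estimate
        logs = np.log10(1.0 / sizes)
        logn = np.log10(counts)
        if sizes.size == 1:
            return 0.0, float(logn[0]), False
        slope = (logn[1] - logn[0]) / (logs[1] - logs[0])
        return float(slope), float(logn[0] - slope * logs[0]), False
    logs = np.log10(1.0 / sizes)
    logn = np.log10(counts)
    slope, intercept = np.polyfit(logs, logn, 1)
    return float(slope), float(intercept), True


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def compute_all(system: RootSystem, n_slices: int = DEFAULT_SLICES,
                s_min: float = BOX_S_MIN) -> AggregateMetrics:
    """All 3D aggregate metrics of one root system.

    Ellipse metrics are 2D-only and remain NaN here; pipelines fill them
    with the mean over the rotational projection series.
    """
    if not system.roots or system.n_segments == 0:
        raise ValueError("empty root system")
    m = AggregateMetrics()
    m.total_length, m.total_area, m.total_volume = totals(system)
    m.max_depth = max_depth(system)
    m.max_width = max_width(system)
    if m.max_depth > 0:
        prof = depth_profile(system, n_slices=n_slices)
        m.median_root_count, m.max_root_count, m.bushiness = count_stats(prof)
        if math.isnan(m.bushiness):
            m.flags["bushiness"] = "zero median count"
        m.volume_distribution = volume_distribution(system)
        if math.isinf(m.volume_distribution):
            m.flags["volume_distribution"] = "no volume below plane"
    else:
        m.flags["depth_profile"] = "zero-depth system"
    hv, ha, degen = convex_hull_3d(system)
    m.convex_hull_volume, m.convex_hull_area = hv, ha
    if degen:
        m.flags["convex_hull"] = "degenerate (coplanar/collinear)"
        m.solidity = float("nan")
        m.flags["solidity"] = "degenerate hull"
    else:
        m.solidity = m.total_volume / hv
    m.fd, m.fa, reliable = fractal_box_count(system, dim=3, s_min=s_min)
    if not reliable:
        m.flags["fractal"] = "fewer than 3 usable box sizes"
    return m
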