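"""Extraction of elementary phenes from a simulated or imported root system.

Phenes reported per axial root class: number of roots, mean diameter,
summed axial length, mean growth angle at 5 cm (degrees from horizontal),
mean measured lateral root branching density (LRBD), summed length and mean
diameter of the subtended laterals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SHORT_NAMES, Root, RootSystem

ANGLE_ARC_CM = 5.0

PHENE_FIELDS = ("n", "diam", "axial_length", "angle", "LRBD",
                "lat_length", "lat_diam")


def angle_at_arc(root: Root, arc: float = ANGLE_ARC_CM):
    """Growth angle from horizontal of the chord base -> point at ``arc``.

    The point is located at arc length ``arc`` along the root polyline
    (linear interpolation inside a segment).  Roots shorter than ``arc``
    fall back to the base->tip chord and are flagged truncated.

    Returns (angle_degrees in [0, 90], truncated: bool).
    """
    truncated = root.length < arc
    p = root.points[-1] if truncated else root.point_at_arc(arc)
    base = root.points[0]
    dy = p[1] - base[1]
    dh = math.hypot(p[0] - base[0], p[2] - base[2])
    if dh < 1e-12 and abs(dy) < 1e-12:
        return 0.0, True
    ang = math.degrees(math.atan2(dy, dh))
    return min(90.0, max(0.0, ang)), truncated


def measure_lrbd(axial_root: Root, laterals: list[Root]) -> float:
    """Laterals per cm of branched zone (first to last branch point).

    With a single lateral the branched zone is the whole root; with none
    the density is 0.
    """
    if axial_root.length <= 0:
        raise ValueError("axial root has zero length")
    k = len(laterals)
    if k == 0:
        return 0.0
    if k == 1:
        return 1.0 / axial_root.length
    arcs = sorted(l.branch_arc for l in laterals)
    zone = arcs[-1] - arcs[0]
    if zone <= 0:
        return 1.0 / axial_root.length
    return k / zone


@dataclass
class ClassPhenes:
    n: int = 0
    diam: float = float("nan")
    axial_length: float = 0.0
    angle: float = float("nan")
    LRBD: float = float("nan")
    lat_length: float = 0.0
    lat_diam: float = float("nan")
    angle_truncated: bool = False


@dataclass
class PheneVector:
    """Per-class elementary phenes of one root system."""

    species: str
    day: float
    classes: dict[str, ClassPhenes] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        """Flat Series with heat-map style names (BW1_n, PR_LRBD, ...)."""
        out = {}
        for cid, cp in self.classes.items():
            short = SHORT_NAMES.get(cid, cid)
            for f in PHENE_FIELDS:
                out[f"{short}_{f}"] = getattr(cp, f)
        return pd.Series(out)


def phene_table(system: RootSystem, arc: float = ANGLE_ARC_CM) -> PheneVector:
    """Aggregate per-class phenes of a root system.

    Class values are means over the roots of the class (angles, diameters,
    LRBD) or class sums (axial and lateral lengths), matching the
    one-value-per-class convention of phenotype heat maps.
    """
    if not system.roots:
        raise ValueError("empty root system")
    pv = PheneVector(species=system.species, day=system.day)
    axials = system.axial_roots()
    by_class: dict[str, list[Root]] = {}
    for r in axials:
        by_class.setdefault(r.class_id, []).append(r)
    for cid, rts in by_class.items():
        cp = ClassPhenes()
        cp.n = len(rts)
        cp.diam = float(np.mean([2.0 * r.radius for r in rts]))
        cp.axial_length = float(sum(r.length for r in rts))
        angles, trunc = [], False
        lrbds = []
        lat_lengths, lat_diams = [], []
        for r in rts:
            a, t = angle_at_arc(r, arc)
            angles.append(a)
            trunc = trunc or t
            lats = system.laterals_of(r.root_id)
            lrbds.append(measure_lrbd(r, lats))
            for l in lats:
                lat_lengths.append(l.length)
                lat_diams.append(2.0 * l.radius)
        cp.angle = float(np.mean(angles))
        cp.angle_truncated = trunc
        cp.LRBD = float(np.mean(lrbds))
        cp.lat_length = float(sum(lat_lengths))
        cp.lat_diam = float(np.mean(lat_diams)) if lat_diams else float("nan")
        pv.classes[cid] = cp
    return pv


def phene_frame(vectors: list[PheneVector],
                ids: list | None = None) -> pd.DataFrame:
    """Stack phene vectors into a phenotype x phene table."""
    rows = [v.to_series() for v in vectors]
    df = pd.DataFrame(rows)
    if ids is not None:
        df.index = ids
    return df
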