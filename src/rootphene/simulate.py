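"""Segment-based functional-structural root simulator.

Root systems are grown as chains of short (<= 0.5 cm) straight segments.
Each root class (bean: primary, basal whorls 1-5, hypocotyl-borne; maize:
primary, seminal, nodal positions 1-4; first-order laterals on every axial
class) is described by a small set of elementary phenes: number of roots,
emergence day, diameter, elongation rate, growth angle at emergence
(degrees from horizontal), gravitropism (degrees of deflection toward the
vertical per cm grown) and lateral root branching density (LRBD,
branches per cm).  Stochasticity enters as multiplicative Gaussian noise on
every continuous phene and as Gaussian angular jitter on growth directions.

Coordinate convention: y is depth (positive downward), the soil surface is
y = 0 and the stem base sits at the origin.  Roots grow without container
boundaries but are clamped to y >= 0 (they cannot re-enter the air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MAX_SEGMENT_LEN = 0.5  # cm; growth steps are subdivided below this
BASE_EXCLUSION = 2.0   # cm of axial root near the base that never branches
TIP_EXCLUSION = 2.0    # cm behind the growing tip that does not branch yet
JITTER_SCALE_DEG = 10.0  # angular jitter sd = stochastic_cv * 10 degrees

BEAN_CLASSES = (
    "primary",
    "basal_whorl_1", "basal_whorl_2", "basal_whorl_3",
    "basal_whorl_4", "basal_whorl_5",
    "hypocotyl_borne",
    "lateral",
)
MAIZE_CLASSES = (
    "primary",
    "seminal",
    "nodal_pos_1", "nodal_pos_2", "nodal_pos_3", "nodal_pos_4",
    "lateral",
)
SPECIES_CLASSES = {"bean": BEAN_CLASSES, "maize": MAIZE_CLASSES}

#: compact column prefixes used in phene tables and CSV headers
SHORT_NAMES = {
    "primary": "PR",
    "basal_whorl_1": "BW1", "basal_whorl_2": "BW2", "basal_whorl_3": "BW3",
    "basal_whorl_4": "BW4", "basal_whorl_5": "BW5",
    "hypocotyl_borne": "HBR",
    "seminal": "SR",
    "nodal_pos_1": "NR1", "nodal_pos_2": "NR2",
    "nodal_pos_3": "NR3", "nodal_pos_4": "NR4",
    "lateral": "LAT",
}


@dataclass
class RootClassParams:
    """Elementary phenes of one root class."""

    class_id: str
    count: int = 1
    emergence_day: float = 0.0
    diameter: float = 0.1          # cm
    growth_rate: float = 1.0       # cm / day
    growth_angle: float = 90.0     # degrees from horizontal at emergence
    gravitropism: float = 0.0      # deg of deflection toward vertical per cm
    lrbd: float = 0.0              # lateral branches per cm (0 for laterals)
    stochastic_cv: float = 0.0     # coefficient of variation of all phenes
    azimuth_offset: float = 0.0    # whorl/node rotation, degrees

    def validate(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.class_id}: count must be >= 0")
        if self.diameter <= 0:
            raise ValueError(f"{self.class_id}: diameter must be > 0")
        if self.growth_rate < 0:
            raise ValueError(f"{self.class_id}: growth_rate must be >= 0")
        if not 0.0 <= self.growth_angle <= 90.0:
            raise ValueError(f"{self.class_id}: growth_angle outside [0, 90]")
        if self.lrbd < 0:
            raise ValueError(f"{self.class_id}: lrbd must be >= 0")
        if self.stochastic_cv < 0:
            raise ValueError(f"{self.class_id}: stochastic_cv must be >= 0")


@dataclass
class PhenotypeSpec:
    """Generative description of one phenotype: classes, seed, carbon proxy.

    ``elongation_budget`` (cm/day, optional) caps the summed daily
    elongation of all tips, proportionally scaling growth when demand
    exceeds it -- a deliberately minimal stand-in for carbon limitation
    that reproduces the more-axials/shorter-laterals trade-off.
    """

    species: str
    classes: list[RootClassParams]
    seed: int = 0
    elongation_budget: float | None = None

    def validate(self) -> None:
        if self.species not in SPECIES_CLASSES:
            raise ValueError(f"unknown species {self.species!r}")
        known = SPECIES_CLASSES[self.species]
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("class_ids must be unique")
        for c in self.classes:
            if c.class_id not in known:
                raise ValueError(
                    f"class {c.class_id!r} unknown for species {self.species!r}")
            c.validate()
        if ids.count("primary") != 1:
            raise ValueError("spec must contain exactly one primary class")

    def class_params(self, class_id: str) -> RootClassParams:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)


class Root:
    """One root: an ordered polyline of segment endpoints plus metadata."""

    __slots__ = (
        "root_id", "class_id", "parent_class", "parent_root_id", "radius",
        "born_day", "branch_arc", "points", "seg_days", "length",
        "direction", "growth_rate", "gravitropism", "jitter_sd",
        "next_branch_arc", "branch_spacing_mean",
    )

    def __init__(self, root_id, class_id, radius, born_day, origin,
                 direction, growth_rate, gravitropism, jitter_sd,
                 parent_class=None, parent_root_id=None, branch_arc=None):
        self.root_id = root_id
        self.class_id = class_id
        self.parent_class = parent_class
        self.parent_root_id = parent_root_id
        self.radius = radius
        self.born_day = born_day
        self.branch_arc = branch_arc  # arc position on the parent, cm
        self.points = [tuple(origin)]
        self.seg_days: list[float] = []
        self.length = 0.0
        self.direction = tuple(direction)
        self.growth_rate = growth_rate
        self.gravitropism = gravitropism
        self.jitter_sd = jitter_sd
        self.next_branch_arc: float | None = None
        self.branch_spacing_mean: float | None = None

    def grow(self, elongation: float, day_end: float, rng) -> None:
        """Extend the tip by ``elongation`` cm, subdividing into segments."""
        if elongation <= 0:
            return
        n_sub = max(1, math.ceil(elongation / MAX_SEGMENT_LEN))
        step = elongation / n_sub
        for _ in range(n_sub):
            self.direction = gravitropism_step(
                self.direction, self.gravitropism, step, rng,
                jitter_sd=self.jitter_sd)
            x, y, z = self.points[-1]
            dx, dy, dz = self.direction
            nx, ny, nz = x + dx * step, y + dy * step, z + dz * step
            if ny < 0.0:  # clamp to the soil surface, stop climbing
                ny = 0.0
                self.direction = _flatten_up(self.direction)
            self.points.append((nx, ny, nz))
            self.seg_days.append(day_end)
            self.length += math.dist((x, y, z), (nx, ny, nz))

    def point_at_arc(self, arc: float) -> tuple[float, float, float]:
        """Linear interpolation at arc length ``arc`` along the polyline."""
        if arc <= 0:
            return self.points[0]
        acc = 0.0
        for a, b in zip(self.points[:-1], self.points[1:]):
            seg = math.dist(a, b)
            if acc + seg >= arc and seg > 0:
                t = (arc - acc) / seg
                return (a[0] + t * (b[0] - a[0]),
                        a[1] + t * (b[1] - a[1]),
                        a[2] + t * (b[2] - a[2]))
            acc += seg
        return self.points[-1]

    def truncated(self, day: float) -> "Root | None":
        """Copy containing only segments grown on or before ``day``."""
        if self.born_day > day + 1e-9:
            return None
        n = 0
        for d in self.seg_days:
            if d <= day + 1e-9:
                n += 1
            else:
                break
        if n == 0:
            return None
        r = Root(self.root_id, self.class_id, self.radius, self.born_day,
                 self.points[0], self.direction, self.growth_rate,
                 self.gravitropism, self.jitter_sd,
                 parent_class=self.parent_class,
                 parent_root_id=self.parent_root_id,
                 branch_arc=self.branch_arc)
        r.points = self.points[:n + 1]
        r.seg_days = self.seg_days[:n]
        r.length = sum(math.dist(a, b)
                       for a, b in zip(r.points[:-1], r.points[1:]))
        return r


class RootSystem:
    """A time-stamped collection of roots; the input of every metric."""

    def __init__(self, species: str, day: float, roots: Sequence[Root]):
        self.species = species
        self.day = day
        self.roots = list(roots)
        self._cache: dict[str, np.ndarray] = {}

    # -- array views -------------------------------------------------------
    def _arrays(self):
        if "starts" not in self._cache:
            starts, ends, radii, days = [], [], [], []
            for r in self.roots:
                pts = r.points
                for i in range(len(pts) - 1):
                    starts.append(pts[i])
                    ends.append(pts[i + 1])
                    radii.append(r.radius)
                    days.append(r.seg_days[i])
            self._cache["starts"] = np.asarray(starts, dtype=float)
            self._cache["ends"] = np.asarray(ends, dtype=float)
            self._cache["radii"] = np.asarray(radii, dtype=float)
            self._cache["days"] = np.asarray(days, dtype=float)
        return (self._cache["starts"], self._cache["ends"],
                self._cache["radii"], self._cache["days"])

    @property
    def n_segments(self) -> int:
        return sum(len(r.points) - 1 for r in self.roots)

    def segment_arrays(self):
        """(starts, ends, radii) arrays of shape (n_segments, 3)/(n,)."""
        s, e, r, _ = self._arrays()
        return s, e, r

    def endpoints(self) -> np.ndarray:
        """All distinct polyline vertices, shape (n, 3)."""
        pts = [p for r in self.roots for p in r.points]
        return np.asarray(pts, dtype=float)

    def axial_roots(self) -> list[Root]:
        return [r for r in self.roots if r.class_id != "lateral"]

    def laterals_of(self, root_id) -> list[Root]:
        return [r for r in self.roots
                if r.class_id == "lateral" and r.parent_root_id == root_id]

    def rotated(self, azimuth_deg: float) -> "RootSystem":
        """Rotate the whole system about the vertical (depth) axis."""
        th = math.radians(azimuth_deg)
        c, s = math.cos(th), math.sin(th)
        out = []
        for r in self.roots:
            nr = Root(r.root_id, r.class_id, r.radius, r.born_day,
                      (0, 0, 0), r.direction, r.growth_rate,
                      r.gravitropism, r.jitter_sd,
                      parent_class=r.parent_class,
                      parent_root_id=r.parent_root_id,
                      branch_arc=r.branch_arc)
            nr.points = [(c * x + s * z, y, -s * x + c * z)
                         for (x, y, z) in r.points]
            nr.seg_days = list(r.seg_days)
            nr.length = r.length
            out.append(nr)
        return RootSystem(self.species, self.day, out)


@dataclass
class RootSystemSeries:
    """Snapshots of one growing phenotype, keyed by simulation day."""

    spec: PhenotypeSpec
    snapshots: dict[float, RootSystem] = field(default_factory=dict)

    @property
    def days(self) -> list[float]:
        return sorted(self.snapshots)

    def __getitem__(self, day) -> RootSystem:
        return self.snapshots[day]


# ---------------------------------------------------------------------------
# elementary growth rules
# ---------------------------------------------------------------------------

def _flatten_up(direction):
    """Remove any upward component from a direction at the soil surface."""
    dx, dy, dz = direction
    if dy >= 0:
        return direction
    h = math.hypot(dx, dz)
    if h < 1e-12:
        return (0.0, 1.0, 0.0)
    return (dx / h, 0.0, dz / h)


def gravitropism_step(direction, gravitropism: float, step_len: float,
                      rng=None, jitter_sd: float = 0.0):
    """Bend a unit growth direction toward the downward vertical.

    The deflection is ``gravitropism * step_len`` degrees, capped at the
    current deviation from vertical, applied in the vertical plane that
    contains ``direction``; optional zero-mean Gaussian angular jitter
    (sd ``jitter_sd`` degrees) is then applied about a uniformly random
    perpendicular axis.
    """
    dx, dy, dz = direction
    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    if step_len <= 0:
        raise ValueError("step_len must be > 0")
    dx, dy, dz = dx / norm, dy / norm, dz / norm

    if gravitropism > 0:
        theta = math.acos(max(-1.0, min(1.0, dy)))  # deviation from vertical
        delta = min(math.radians(gravitropism * step_len), theta)
        if delta > 0 and theta > 1e-12:
            nt = theta - delta
            h = math.hypot(dx, dz)
            if h < 1e-12:  # pointing straight up: bend in an arbitrary plane
                ux, uz = 1.0, 0.0
            else:
                ux, uz = dx / h, dz / h
            st, ct = math.sin(nt), math.cos(nt)
            dx, dy, dz = st * ux, ct, st * uz

    if jitter_sd > 0 and rng is not None:
        eps = math.radians(rng.normal(0.0, jitter_sd))
        psi = rng.uniform(0.0, 2.0 * math.pi)
        ux, uy, uz = _perpendicular(dx, dy, dz, psi)
        ce, se = math.cos(eps), math.sin(eps)
        dx, dy, dz = (dx * ce + ux * se, dy * ce + uy * se, dz * ce + uz * se)
        n = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx, dy, dz = dx / n, dy / n, dz / n
    return (dx, dy, dz)


def _perpendicular(dx, dy, dz, psi):
    """Unit vector perpendicular to d, at azimuth psi in the normal plane."""
    # any helper axis not parallel to d
    if abs(dy) < 0.9:
        ax, ay, az = 0.0, 1.0, 0.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    # u = normalize(a x d), v = d x u
    ux, uy, uz = ay * dz - az * dy, az * dx - ax * dz, ax * dy - ay * dx
    n = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / n, uy / n, uz / n
    vx, vy, vz = dy * uz - dz * uy, dz * ux - dx * uz, dx * uy - dy * ux
    c, s = math.cos(psi), math.sin(psi)
    return (c * ux + s * vx, c * uy + s * vy, c * uz + s * vz)


def azimuth_layout(count: int, offset: float = 0.0) -> list[float]:
    """Evenly spaced azimuths for one whorl/node, rotated by ``offset``."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return [(offset + 360.0 * k / count) % 360.0 for k in range(count)]


def branch_positions(length: float, lrbd: float, cv: float, rng,
                     base_exclusion: float = BASE_EXCLUSION,
                     tip_exclusion: float = TIP_EXCLUSION) -> list[float]:
    """Arc-length positions of lateral branch points on an axial root.

    Spacing averages 1/lrbd with multiplicative jitter; branching starts
    after a basal non-branching zone and stays ``tip_exclusion`` behind the
    tip.  Used for testing; the simulator applies the same rule
    incrementally as roots grow.
    """
    if lrbd < 0:
        raise ValueError("lrbd must be >= 0")
    if lrbd == 0:
        return []
    out = []
    pos = base_exclusion
    while True:
        gap = (1.0 / lrbd)
        if cv > 0 and rng is not None:
            gap *= max(0.05, 1.0 + cv * rng.normal())
        pos += gap
        if pos > length - tip_exclusion + 1e-9:
            break
        out.append(pos)
    return out


def _initial_direction(growth_angle_deg: float, azimuth_deg: float):
    a = math.radians(growth_angle_deg)
    phi = math.radians(azimuth_deg)
    ca = math.cos(a)
    return (math.cos(phi) * ca, math.sin(a), math.sin(phi) * ca)


def _jitter(value: float, cv: float, rng, floor: float = 1e-6) -> float:
    if cv <= 0:
        return value
    return max(floor, value * (1.0 + cv * rng.normal()))


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate(spec: PhenotypeSpec, end_day: float = 40.0,
             dt: float = 0.5) -> RootSystemSeries:
    """Grow a phenotype and return snapshots at days 10, 15, ... end_day.

    Axial roots emerge from the stem base (origin) at their class emergence
    day, directed by their growth angle and a deterministic whorl azimuth
    layout; tips elongate ``growth_rate * dt`` per step (subdivided so no
    segment exceeds 0.5 cm) with the direction updated by the gravitropism
    rule plus stochastic jitter; laterals are emitted along the branched
    zone at mean spacing 1/LRBD.  There are no container boundaries; the
    only geometric constraint is the soil surface (y >= 0).
    """
    if dt <= 0 or dt > 1:
        raise ValueError("dt must be in (0, 1]")
    if end_day < 10:
        raise ValueError("end_day must be >= 10")
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    lat_params = None
    for c in spec.classes:
        if c.class_id == "lateral":
            lat_params = c

    roots: list[Root] = []
    next_id = 0
    # axial roots are created up front (deterministic order) so that RNG
    # consumption does not depend on dt discretisation of emergence
    axials: list[Root] = []
    for c in spec.classes:
        if c.class_id == "lateral" or c.count == 0:
            continue
        azimuths = azimuth_layout(c.count, c.azimuth_offset)
        for az in azimuths:
            ang = min(90.0, _jitter(c.growth_angle, c.stochastic_cv, rng)) \
                if c.stochastic_cv > 0 else c.growth_angle
            if c.stochastic_cv > 0:
                az = az + c.stochastic_cv * 30.0 * rng.normal()
            r = Root(
                root_id=next_id,
                class_id=c.class_id,
                radius=_jitter(c.diameter, c.stochastic_cv, rng) / 2.0,
                born_day=c.emergence_day,
                origin=(0.0, 0.0, 0.0),
                direction=_initial_direction(ang, az),
                growth_rate=_jitter(c.growth_rate, c.stochastic_cv, rng),
                gravitropism=c.gravitropism,
                jitter_sd=c.stochastic_cv * JITTER_SCALE_DEG,
            )
            if c.lrbd > 0 and lat_params is not None:
                spacing = 1.0 / c.lrbd
                r.branch_spacing_mean = spacing
                gap = spacing if c.stochastic_cv <= 0 else \
                    spacing * max(0.05, 1.0 + c.stochastic_cv * rng.normal())
                r.next_branch_arc = BASE_EXCLUSION + gap
            next_id += 1
            axials.append(r)
    roots.extend(axials)

    n_steps = round(end_day / dt)
    snap_days = [d for d in range(10, int(end_day) + 1, 5)]
    series = RootSystemSeries(spec=spec)

    for k in range(n_steps):
        t0 = k * dt
        t1 = (k + 1) * dt
        active = [r for r in roots if r.born_day <= t0 + 1e-9]
        scale = 1.0
        if spec.elongation_budget is not None:
            demand = sum(r.growth_rate for r in active)
            if demand > spec.elongation_budget > 0:
                scale = spec.elongation_budget / demand
        new_laterals: list[Root] = []
        for r in active:
            r.grow(r.growth_rate * dt * scale, t1, rng)
            if r.next_branch_arc is not None and lat_params is not None:
                cv = lat_params.stochastic_cv
                while r.next_branch_arc <= r.length - TIP_EXCLUSION + 1e-9:
                    arc = r.next_branch_arc
                    origin = r.point_at_arc(arc)
                    lat_dir = _lateral_direction(r, arc, rng)
                    lat = Root(
                        root_id=next_id,
                        class_id="lateral",
                        radius=_jitter(lat_params.diameter, cv, rng) / 2.0,
                        born_day=t1,
                        origin=origin,
                        direction=lat_dir,
                        growth_rate=_jitter(lat_params.growth_rate, cv, rng),
                        gravitropism=lat_params.gravitropism,
                        jitter_sd=cv * JITTER_SCALE_DEG,
                        parent_class=r.class_id,
                        parent_root_id=r.root_id,
                        branch_arc=arc,
                    )
                    next_id += 1
                    new_laterals.append(lat)
                    gap = r.branch_spacing_mean
                    pcv = _parent_cv(spec, r.class_id)
                    if pcv > 0:
                        gap = gap * max(0.05, 1.0 + pcv * rng.normal())
                    r.next_branch_arc = arc + gap
        roots.extend(new_laterals)

    for d in snap_days:
        snap_roots = []
        for r in roots:
            tr = r.truncated(d)
            if tr is not None and tr.length > 0:
                snap_roots.append(tr)
        series.snapshots[float(d)] = RootSystem(spec.species, float(d),
                                                snap_roots)
    return series


def _parent_cv(spec: PhenotypeSpec, class_id: str) -> float:
    try:
        return spec.class_params(class_id).stochastic_cv
    except KeyError:
        return 0.0


def _lateral_direction(parent: Root, arc: float, rng):
    """Initial lateral direction: perpendicular to the local axial
    direction at a uniformly random azimuth around it."""
    # local tangent at the branch point
    pts = parent.points
    acc, tangent = 0.0, parent.direction
    for a, b in zip(pts[:-1], pts[1:]):
        seg = math.dist(a, b)
        if acc + seg >= arc and seg > 1e-12:
            tangent = ((b[0] - a[0]) / seg, (b[1] - a[1]) / seg,
                       (b[2] - a[2]) / seg)
            break
        acc += seg
    psi = rng.uniform(0.0, 2.0 * math.pi)
    d = _perpendicular(*tangent, psi)
    if d[1] < 0:  # do not start growing upward
        d = (d[0], -d[1], d[2])
    return d


def emit_laterals(axial_root: Root, lrbd: float, lateral_params:
                  RootClassParams, rng) -> list[Root]:
    """One-shot lateral emission along a finished axial root.

    The incremental rule inside :func:`simulate` is the production path;
    this standalone form exists for direct use on externally built roots.
    """
    if lrbd < 0:
        raise ValueError("lrbd must be >= 0")
    cv = lateral_params.stochastic_cv
    positions = branch_positions(axial_root.length, lrbd, cv, rng)
    out = []
    for i, arc in enumerate(positions):
        origin = axial_root.point_at_arc(arc)
        d = _lateral_direction(axial_root, arc, rng)
        lat = Root(root_id=(axial_root.root_id, "lat", i),
                   class_id="lateral",
                   radius=_jitter(lateral_params.diameter, cv, rng) / 2.0,
                   born_day=axial_root.born_day,
                   origin=origin, direction=d,
                   growth_rate=_jitter(lateral_params.growth_rate, cv, rng),
                   gravitropism=lateral_params.gravitropism,
                   jitter_sd=cv * JITTER_SCALE_DEG,
                   parent_class=axial_root.class_id,
                   parent_root_id=axial_root.root_id,
                   branch_arc=arc)
        out.append(lat)
    return out


# ---------------------------------------------------------------------------
# phenotype sampling
# ---------------------------------------------------------------------------

@dataclass
class PheneRange:
    lo: float
    hi: float
    integer: bool = False

    def sample(self, rng) -> float:
        if self.lo > self.hi:
            raise ValueError("range lo > hi")
        if self.integer:
            return int(rng.integers(int(self.lo), int(self.hi) + 1))
        return float(rng.uniform(self.lo, self.hi))


def sample_phenotypes(ranges: dict[str, dict[str, PheneRange]],
                      template: PhenotypeSpec, n: int,
                      seed: int) -> list[PhenotypeSpec]:
    """Draw ``n`` phenotype specs with phenes uniform over per-class ranges.

    ``ranges`` maps class_id -> field name -> PheneRange; fields not listed
    keep the template value.  Integer phenes (counts) are drawn uniformly
    over the integer range.  Reproducible from ``seed``; per-spec simulation
    seeds are spawned deterministically so batches are order-independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not ranges:
        raise ValueError("empty ranges")
    template.validate()
    specs = []
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        classes = []
        for c in template.classes:
            c2 = replace(c)
            for fieldname, rg in ranges.get(c.class_id, {}).items():
                setattr(c2, fieldname, rg.sample(rng))
            c2.count = int(c2.count)
            classes.append(c2)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(PhenotypeSpec(
            species=template.species, classes=classes, seed=sim_seed,
            elongation_budget=template.elongation_budget))
    return specs
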