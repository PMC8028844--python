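"""Shared fixtures: hand-built root systems and tiny phenotype specs."""

import math

import numpy as np
import pytest

from rootphene.simulate import (PhenotypeSpec, Root, RootClassParams,
                                RootSystem)


def make_root(points, radius=0.05, class_id="primary", root_id=0,
              born_day=0.0, parent_root_id=None, branch_arc=None,
              parent_class=None):
    """Build a Root directly from a polyline (cm)."""
    r = Root(root_id=root_id, class_id=class_id, radius=radius,
             born_day=born_day, origin=points[0], direction=(0.0, 1.0, 0.0),
             growth_rate=0.0, gravitropism=0.0, jitter_sd=0.0,
             parent_class=parent_class, parent_root_id=parent_root_id,
             branch_arc=branch_arc)
    r.points = [tuple(p) for p in points]
    r.seg_days = [born_day] * (len(points) - 1)
    r.length = sum(math.dist(a, b) for a, b in zip(r.points[:-1],
                                                   r.points[1:]))
    return r


def make_system(roots, species="bean", day=10.0):
    return RootSystem(species, day, roots)


@pytest.fixture
def vertical_rod():
    """Single straight vertical root, 10 cm, radius 0.05."""
    pts = [(0, i * 0.5, 0) for i in range(21)]
    return make_system([make_root(pts)])


@pytest.fixture
def toy_three_root():
    """Three roots spanning a 3D volume; used against brute-force oracles."""
    r1 = make_root([(0, 0, 0), (0, 2, 0), (0.5, 4, 0.5), (1, 6, 1)],
                   radius=0.06, root_id=0)
    r2 = make_root([(0, 0, 0), (2, 1, 0), (4, 2, -1), (5, 2.5, -2)],
                   radius=0.04, class_id="basal_whorl_1", root_id=1)
    r3 = make_root([(0, 0, 0), (-1, 1.5, 1), (-2, 3, 2), (-2.5, 5, 2.5)],
                   radius=0.05, class_id="basal_whorl_1", root_id=2)
    return make_system([r1, r2, r3])


def random_system(rng, n_roots=6, n_pts=12, scale=8.0):
    """Random polyline systems (roots from the origin, y >= 0)."""
    roots = []
    for i in range(n_roots):
        steps = rng.normal(size=(n_pts, 3)) * scale / n_pts
        pts = np.cumsum(np.vstack([[0, 0, 0], steps]), axis=0)
        pts[:, 1] = np.abs(pts[:, 1])  # keep below the surface
        roots.append(make_root(pts, radius=0.03 + 0.05 * rng.random(),
                               root_id=i))
    return make_system(roots)


def straight_spec(angle=90.0, gravitropism=0.0, growth_rate=1.0,
                  lrbd=0.0, cv=0.0, seed=1, species="bean",
                  lateral_kwargs=None):
    classes = [RootClassParams("primary", count=1, diameter=0.1,
                               growth_rate=growth_rate, growth_angle=angle,
                               gravitropism=gravitropism, lrbd=lrbd,
                               stochastic_cv=cv)]
    if lrbd > 0:
        lk = dict(diameter=0.03, growth_rate=0.3, gravitropism=1.0,
                  stochastic_cv=cv)
        lk.update(lateral_kwargs or {})
        classes.append(RootClassParams("lateral", **lk))
    return PhenotypeSpec(species, classes, seed=seed)


def recovery_spec(seed=1, cv=0.0):
    """A bean spec with gravitropism 0 everywhere: every phene should be
    measurable back exactly when cv = 0."""
    classes = [
        RootClassParams("primary", count=1, emergence_day=0.0, diameter=0.12,
                        growth_rate=2.0, growth_angle=90.0, gravitropism=0.0,
                        lrbd=2.0, stochastic_cv=cv),
        RootClassParams("basal_whorl_1", count=4, emergence_day=1.0,
                        diameter=0.08, growth_rate=1.5, growth_angle=45.0,
                        gravitropism=0.0, lrbd=1.0, stochastic_cv=cv),
        RootClassParams("basal_whorl_2", count=3, emergence_day=2.0,
                        diameter=0.06, growth_rate=1.2, growth_angle=20.0,
                        gravitropism=0.0, lrbd=0.0, stochastic_cv=cv,
                        azimuth_offset=30.0),
        RootClassParams("lateral", diameter=0.03, growth_rate=0.4,
                        growth_angle=0.0, gravitropism=0.0,
                        stochastic_cv=cv),
    ]
    return PhenotypeSpec("bean", classes, seed=seed)
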