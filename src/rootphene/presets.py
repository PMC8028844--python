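"""Default bean and maize architectures and phene sampling ranges.

The numbers below define plausible glasshouse-scale phenotypes: a bean
(*Phaseolus vulgaris*) root system with a taproot, up to five basal-root
whorls of four roots and a few shallow hypocotyl-borne roots, and a maize
(*Zea mays*) system with a primary root, seminal roots and nodal (crown)
roots emerging from successive stem nodes over time.  They are configurable
defaults, not canonical values: sampling ranges are wide enough to span
shallow/deep, sparse/bushy architectures.
"""

from __future__ import annotations

from .simulate import PheneRange, PhenotypeSpec, RootClassParams


def bean_template(seed: int = 0, cv: float = 0.1,
                  elongation_budget: float | None = None) -> PhenotypeSpec:
    classes = [
        RootClassParams("primary", count=1, emergence_day=0.0,
                        diameter=0.15, growth_rate=2.2, growth_angle=90.0,
                        gravitropism=3.0, lrbd=2.0, stochastic_cv=cv),
        RootClassParams("basal_whorl_1", count=4, emergence_day=1.0,
                        diameter=0.09, growth_rate=1.6, growth_angle=55.0,
                        gravitropism=1.0, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=0.0),
        RootClassParams("basal_whorl_2", count=4, emergence_day=1.5,
                        diameter=0.08, growth_rate=1.5, growth_angle=40.0,
                        gravitropism=1.0, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=45.0),
        RootClassParams("basal_whorl_3", count=4, emergence_day=2.0,
                        diameter=0.08, growth_rate=1.4, growth_angle=25.0,
                        gravitropism=0.8, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=22.5),
        RootClassParams("basal_whorl_4", count=0, emergence_day=2.5,
                        diameter=0.07, growth_rate=1.3, growth_angle=15.0,
                        gravitropism=0.8, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=67.5),
        RootClassParams("hypocotyl_borne", count=2, emergence_day=5.0,
                        diameter=0.06, growth_rate=1.0, growth_angle=10.0,
                        gravitropism=0.5, lrbd=1.0, stochastic_cv=cv,
                        azimuth_offset=30.0),
        RootClassParams("lateral", count=0, diameter=0.03, growth_rate=0.35,
                        growth_angle=0.0, gravitropism=1.0, lrbd=0.0,
                        stochastic_cv=cv),
    ]
    return PhenotypeSpec("bean", classes, seed=seed,
                         elongation_budget=elongation_budget)


def maize_template(seed: int = 0, cv: float = 0.1,
                   elongation_budget: float | None = None) -> PhenotypeSpec:
    classes = [
        RootClassParams("primary", count=1, emergence_day=0.0,
                        diameter=0.12, growth_rate=2.5, growth_angle=90.0,
                        gravitropism=3.0, lrbd=3.0, stochastic_cv=cv),
        RootClassParams("seminal", count=4, emergence_day=1.0,
                        diameter=0.07, growth_rate=1.8, growth_angle=50.0,
                        gravitropism=1.5, lrbd=3.0, stochastic_cv=cv,
                        azimuth_offset=18.0),
        RootClassParams("nodal_pos_1", count=3, emergence_day=6.0,
                        diameter=0.09, growth_rate=1.8, growth_angle=40.0,
                        gravitropism=1.5, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=0.0),
        RootClassParams("nodal_pos_2", count=4, emergence_day=10.0,
                        diameter=0.10, growth_rate=1.9, growth_angle=35.0,
                        gravitropism=1.5, lrbd=2.0, stochastic_cv=cv,
                        azimuth_offset=30.0),
        RootClassParams("nodal_pos_3", count=5, emergence_day=14.0,
                        diameter=0.12, growth_rate=2.0, growth_angle=30.0,
                        gravitropism=1.2, lrbd=1.5, stochastic_cv=cv,
                        azimuth_offset=60.0),
        RootClassParams("nodal_pos_4", count=6, emergence_day=18.0,
                        diameter=0.13, growth_rate=2.0, growth_angle=25.0,
                        gravitropism=1.0, lrbd=1.5, stochastic_cv=cv,
                        azimuth_offset=90.0),
        RootClassParams("lateral", count=0, diameter=0.025, growth_rate=0.3,
                        growth_angle=0.0, gravitropism=1.0, lrbd=0.0,
                        stochastic_cv=cv),
    ]
    return PhenotypeSpec("maize", classes, seed=seed,
                         elongation_budget=elongation_budget)


def bean_ranges() -> dict[str, dict[str, PheneRange]]:
    """Wide sampling ranges over the varied phenes (counts, angles,
    diameters, LRBD), one entry per axial class."""
    whorl = lambda: {
        "count": PheneRange(0, 4, integer=True),
        "growth_angle": PheneRange(10, 80),
        "diameter": PheneRange(0.05, 0.12),
        "lrbd": PheneRange(0.5, 4.0),
        "growth_rate": PheneRange(1.0, 2.0),
    }
    return {
        "primary": {"diameter": PheneRange(0.10, 0.20),
                    "lrbd": PheneRange(0.5, 4.0),
                    "growth_rate": PheneRange(1.8, 2.8)},
        "basal_whorl_1": whorl(),
        "basal_whorl_2": whorl(),
        "basal_whorl_3": whorl(),
        "basal_whorl_4": whorl(),
        "hypocotyl_borne": {"count": PheneRange(0, 3, integer=True),
                            "growth_angle": PheneRange(5, 30),
                            "lrbd": PheneRange(0.2, 2.0)},
        "lateral": {"diameter": PheneRange(0.02, 0.04),
                    "growth_rate": PheneRange(0.2, 0.5)},
    }


def maize_ranges() -> dict[str, dict[str, PheneRange]]:
    node = lambda lo, hi: {
        "count": PheneRange(lo, hi, integer=True),
        "growth_angle": PheneRange(15, 70),
        "diameter": PheneRange(0.06, 0.15),
        "lrbd": PheneRange(0.5, 4.0),
        "growth_rate": PheneRange(1.2, 2.4),
    }
    return {
        "primary": {"diameter": PheneRange(0.08, 0.16),
                    "lrbd": PheneRange(0.5, 4.0),
                    "growth_rate": PheneRange(2.0, 3.0)},
        "seminal": {"count": PheneRange(0, 6, integer=True),
                    "growth_angle": PheneRange(20, 70),
                    "diameter": PheneRange(0.05, 0.10),
                    "lrbd": PheneRange(0.5, 4.0),
                    "growth_rate": PheneRange(1.2, 2.2)},
        "nodal_pos_1": node(1, 4),
        "nodal_pos_2": node(2, 5),
        "nodal_pos_3": node(2, 6),
        "nodal_pos_4": node(3, 7),
        "lateral": {"diameter": PheneRange(0.015, 0.035),
                    "growth_rate": PheneRange(0.2, 0.45)},
    }


def template_for(species: str, **kw) -> PhenotypeSpec:
    if species == "bean":
        return bean_template(**kw)
    if species == "maize":
        return maize_template(**kw)
    raise ValueError(f"unknown species {species!r}")


def ranges_for(species: str) -> dict[str, dict[str, PheneRange]]:
    return bean_ranges() if species == "bean" else maize_ranges()
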