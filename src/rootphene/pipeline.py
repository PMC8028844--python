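"""Batch orchestration: simulate -> measure -> project -> analyze.

A single master seed expands deterministically into per-phenotype seeds
(counter-based SeedSequence spawning) so batches are order-independent and
resumable: each phenotype writes a shard CSV which is skipped if present.
The missing-value sentinel in every CSV is "NA".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .metrics import compute_all
from .phenes import phene_table
from .projection import series as projection_series
from .rsml import write_rsml
from .simulate import PheneRange, PhenotypeSpec, sample_phenotypes, simulate

NA = "NA"


@dataclass
class RunConfig:
    species: str = "bean"
    n_phenotypes: int = 10
    seed: int = 0
    end_day: float = 40.0
    dt: float = 0.5
    days: tuple = (10, 15, 20, 25, 30, 35, 40)
    projection_step: float = 20.0
    n_slices: int = 50
    box_s_min: float = 0.2
    stochastic_cv: float = 0.1
    elongation_budget: float | None = None
    rf_ntree: int = 1000
    rf_mtry: int = 8
    rf_repeats: int = 50
    write_rsml: bool = False
    out_dir: str = "results/run"
    ranges: dict = field(default_factory=dict)  # optional range overrides

    def validate(self) -> None:
        if self.species not in ("bean", "maize"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.n_phenotypes < 1:
            raise ValueError("n_phenotypes must be >= 1")
        if self.end_day < 10:
            raise ValueError("end_day must be >= 10")
        if 360.0 % self.projection_step:
            raise ValueError("projection_step must divide 360")
        bad = [d for d in self.days if d > self.end_day]
        if bad:
            raise ValueError(f"days {bad} exceed end_day")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def build_specs(cfg: RunConfig) -> list[PhenotypeSpec]:
    template = presets.template_for(cfg.species, cv=cfg.stochastic_cv,
                                    elongation_budget=cfg.elongation_budget)
    ranges = presets.ranges_for(cfg.species)
    for cid, fields_ in cfg.ranges.items():
        for f, lohi in fields_.items():
            ranges.setdefault(cid, {})[f] = PheneRange(
                lohi[0], lohi[1], integer=(f == "count"))
    return sample_phenotypes(ranges, template, cfg.n_phenotypes, cfg.seed)


def measure_phenotype(spec: PhenotypeSpec, cfg: RunConfig,
                      pheno_id: int, out_dir: Path | None = None):
    """Simulate one phenotype and measure phenes, 3D metrics and the
    projection series at every requested day.  Returns (phene rows,
    metric rows) as lists of dicts."""
    ser = simulate(spec, end_day=cfg.end_day, dt=cfg.dt)
    phene_rows, metric_rows = [], []
    for day in cfg.days:
        system = ser[float(day)]
        if out_dir is not None and cfg.write_rsml:
            rdir = out_dir / "rsml"
            rdir.mkdir(parents=True, exist_ok=True)
            write_rsml(system, rdir / f"pheno{pheno_id:04d}_day{day}.rsml")
        pv = phene_table(system)
        prow = pv.to_series().to_dict()
        prow.update(phenotype=pheno_id, day=day, seed=spec.seed)
        phene_rows.append(prow)

        m3 = compute_all(system, n_slices=cfg.n_slices, s_min=cfg.box_s_min)
        proj = projection_series(system, step=cfg.projection_step,
                                 n_slices=cfg.n_slices, s_min=cfg.box_s_min)
        # ellipse metrics exist only in 2D: fill the 3D record with the
        # rotational-series means
        m3.ellipse_major = float(proj.mean["ellipse_major"])
        m3.ellipse_minor = float(proj.mean["ellipse_minor"])
        m3.ellipse_aspect = float(proj.mean["ellipse_aspect"])
        row3 = m3.to_dict()
        row3.update(phenotype=pheno_id, day=day, representation="3D")
        metric_rows.append(row3)
        row2 = proj.mean.to_dict()
        row2.update(phenotype=pheno_id, day=day,
                    representation="projection-mean")
        metric_rows.append(row2)
        rowcv = proj.cv.to_dict()
        rowcv.update(phenotype=pheno_id, day=day,
                     representation="projection-cv")
        metric_rows.append(rowcv)
    return phene_rows, metric_rows


def run_batch(cfg: RunConfig, verbose: bool = False) -> Path:
    """Run the full simulate/measure stage for a batch; resumable."""
    cfg.validate()
    out = Path(cfg.out_dir)
    shards = out / "shards"
    shards.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    specs = build_specs(cfg)
    for i, spec in enumerate(specs):
        shard = shards / f"pheno{i:04d}.json"
        if shard.exists():
            continue
        phene_rows, metric_rows = measure_phenotype(spec, cfg, i, out)
        shard.write_text(json.dumps(
            {"phenes": phene_rows, "metrics": metric_rows}, default=float))
        if verbose:
            print(f"phenotype {i + 1}/{len(specs)} done")
    phenes, metrics = [], []
    for i in range(len(specs)):
        data = json.loads((shards / f"pheno{i:04d}.json").read_text())
        phenes.extend(data["phenes"])
        metrics.extend(data["metrics"])
    pdf = pd.DataFrame(phenes)
    mdf = pd.DataFrame(metrics)
    pdf.to_csv(out / "phenes.csv", index=False, na_rep=NA)
    mdf.to_csv(out / "metrics.csv", index=False, na_rep=NA)
    return out


def load_batch(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    pdf = pd.read_csv(out / "phenes.csv", na_values=NA)
    mdf = pd.read_csv(out / "metrics.csv", na_values=NA)
    return pdf, mdf


def phenotype_matrix(phenes: pd.DataFrame, metrics: pd.DataFrame,
                     day: float, representation: str = "3D"):
    """Merge phene predictors and metric responses for one day.

    Returns (X, Y): X has the phene columns (constant and all-NaN columns
    dropped, remaining NaN filled with 0 -- absent classes have no
    laterals/angles), Y the 17 aggregate metric columns.
    """
    p = phenes[phenes["day"] == day].set_index("phenotype")
    m = metrics[(metrics["day"] == day) &
                (metrics["representation"] == representation)]
    m = m.set_index("phenotype")
    from .metrics import AggregateMetrics
    ycols = [c for c in AggregateMetrics.METRIC_NAMES if c in m.columns]
    xcols = [c for c in p.columns if c not in ("day", "seed")]
    X = p[xcols].astype(float)
    X = X.dropna(axis=1, how="all").fillna(0.0)
    X = X.loc[:, X.std() > 0]
    Y = m[ycols].astype(float)
    common = X.index.intersection(Y.index)
    return X.loc[common], Y.loc[common]
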