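"""How much does each metric vary across 2D views of the same root system?

Summarises the per-phenotype coefficient of variation of every metric
across the 18-view rotational projection series (already computed by the
batch pipeline as the 'projection-cv' representation).  Expected result:
angle and the shape metrics built on it (hull area/perimeter, ellipse
axes, aspect, solidity, FD/FA) vary by roughly 5-20% across views while
depth and count metrics are essentially view-independent -- the reason 2D
imaging platforms misestimate exactly the shape-driven aggregates.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rootphene.pipeline import load_batch


SENSITIVE = ("convex_hull_volume", "convex_hull_area", "ellipse_major",
             "ellipse_minor", "ellipse_aspect", "solidity", "fd", "fa")
STABLE = ("max_depth", "median_root_count", "max_root_count")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--day", type=float, default=20.0)
    args = ap.parse_args()

    for species in ("bean", "maize"):
        batch = Path(args.results) / f"batch_{species}"
        if not batch.exists():
            print(f"skipping {species}: no batch at {batch}")
            continue
        _, metrics = load_batch(batch)
        cv = metrics[(metrics["day"] == args.day) &
                     (metrics["representation"] == "projection-cv")]
        cv = cv.set_index("phenotype").select_dtypes("number").abs()
        summary = cv.median().rename("median_cv").to_frame()
        summary["q90_cv"] = cv.quantile(0.9)
        summary.to_csv(batch / "projection_cv_summary.csv", na_rep="NA")
        ms = float(np.nanmedian(cv[[c for c in SENSITIVE
                                    if c in cv]].to_numpy()))
        mt = float(np.nanmedian(cv[[c for c in STABLE
                                    if c in cv]].to_numpy()))
        print(f"{species}: median view-CV shape/angle metrics {ms:.3f} "
              f"vs depth/count metrics {mt:.3g}")


if __name__ == "__main__":
    main()
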