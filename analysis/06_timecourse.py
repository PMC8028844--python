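"""Which metrics are stable over a growth period and which are not?

Classifies every metric's day-10..40 trajectory per phenotype as
increasing / static / decreasing / neither (Spearman rho against day).
Expected result: size and extent aggregates (total length/area/volume,
depth, hull, FA) increase monotonically; the elementary phenes (counts,
diameters, angles, LRBD) are static once all root classes have emerged --
the temporal-stability argument for phene-level phenotyping.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from rootphene.analysis import timecourse
from rootphene.pipeline import load_batch


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    for species in ("bean", "maize"):
        batch = Path(args.results) / f"batch_{species}"
        if not batch.exists():
            print(f"skipping {species}: no batch at {batch}")
            continue
        phenes, metrics = load_batch(batch)
        m3 = metrics[metrics["representation"] == "3D"]
        if m3["day"].nunique() < 3:
            print(f"{species}: need >=3 snapshot days for trajectories")
            continue
        rows = []
        for pid, sub in m3.groupby("phenotype"):
            t = timecourse(sub.drop(columns=["phenotype",
                                             "representation"]))
            t.insert(0, "phenotype", pid)
            rows.append(t)
        for pid, sub in phenes.groupby("phenotype"):
            t = timecourse(sub.drop(columns=["phenotype", "seed"]))
            t.insert(0, "phenotype", pid)
            rows.append(t)
        out = pd.concat(rows)
        out.to_csv(batch / "timecourse_classes.csv", index=False,
                   na_rep="NA")
        print(f"{species}:")
        for metric, sub in out.groupby("metric"):
            counts = Counter(sub["trajectory"])
            top = counts.most_common(1)[0]
            print(f"  {metric:<24s} mostly {top[0]} "
                  f"({top[1]}/{len(sub)} phenotypes)")


if __name__ == "__main__":
    main()
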