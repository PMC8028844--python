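"""Do near-identical aggregate metrics imply near-identical phenotypes?

Finds groups of phenotypes whose convex hull volume (shape aggregate) or
fractal dimension (complexity aggregate) match within a tolerance and
reports how far apart their phenes are on the min-max scale.  A large
within-group phene range demonstrates that the aggregate metric is a
degenerate (non-unique) summary of the phenotype.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rootphene.analysis import aggregate_degeneracy_search
from rootphene.pipeline import load_batch


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--day", type=float, default=20.0)
    ap.add_argument("--tol", type=float, default=0.01,
                    help="relative tolerance for 'matched' metric values")
    args = ap.parse_args()

    for species in ("bean", "maize"):
        batch = Path(args.results) / f"batch_{species}"
        if not batch.exists():
            print(f"skipping {species}: no batch at {batch}")
            continue
        phenes, metrics = load_batch(batch)
        m = metrics[(metrics["day"] == args.day) &
                    (metrics["representation"] == "3D")]
        m = m.set_index("phenotype")
        p = phenes[phenes["day"] == args.day].set_index("phenotype")
        p = p.drop(columns=["day", "seed"]).fillna(0.0)
        rows = []
        for metric in ("convex_hull_volume", "fd"):
            vals = m[metric].replace([np.inf, -np.inf], np.nan).dropna()
            groups = aggregate_degeneracy_search(vals, p.loc[vals.index],
                                                 tol=args.tol)
            for g in groups:
                rows.append({
                    "metric": metric, "reference": g.reference,
                    "n_members": len(g.members),
                    "metric_spread": g.metric_values.max()
                    - g.metric_values.min(),
                    "max_scaled_phene_range": g.max_range,
                    "most_divergent_phene": g.phene_range.idxmax(),
                })
            big = [g for g in groups if g.max_range >= 0.5]
            print(f"{species}/{metric}: {len(groups)} matched groups "
                  f"(tol {args.tol:.0%}), {len(big)} with a phene "
                  f"differing by >=0.5 of its batch range")
        pd.DataFrame(rows).to_csv(batch / "degeneracy_groups.csv",
                                  index=False, na_rep="NA")


if __name__ == "__main__":
    main()
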