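"""Repeated random-forest regression of every aggregate metric on the
phene table: which phenes explain which aggregate?

For each aggregate metric (response) the forest is refit repeatedly, OOB
permutation importances are pooled, significant phenes are selected and a
reduced model refit.  Writes an importance summary (full/reduced OOB R^2,
selected phenes) and the per-repeat importance samples.  Expected
structure: axial/lateral length variables matter everywhere; angle
variables enter for width/hull/ellipse metrics; diameter for volume and
solidity.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rootphene.analysis import importance_summary, rf_importance
from rootphene.pipeline import load_batch, phenotype_matrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--day", type=float, default=20.0)
    ap.add_argument("--ntree", type=int, default=200)
    ap.add_argument("--repeats", type=int, default=10)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    for species in ("bean", "maize"):
        batch = Path(args.results) / f"batch_{species}"
        if not batch.exists():
            print(f"skipping {species}: no batch at {batch}")
            continue
        phenes, metrics = load_batch(batch)
        X, Y = phenotype_matrix(phenes, metrics, day=args.day)
        results, samples = [], []
        for col in Y.columns:
            y = Y[col].replace([np.inf, -np.inf], np.nan).dropna()
            if len(y) < 10 or y.std() == 0:
                continue
            res = rf_importance(X.loc[y.index], y, response=col,
                                n_repeats=args.repeats, ntree=args.ntree,
                                seed=args.seed)
            results.append(res)
            df = pd.DataFrame(res.samples, columns=res.predictors)
            df.insert(0, "metric", col)
            df.insert(1, "repeat", range(len(df)))
            samples.append(df)
        if not results:
            print(f"{species}: too few usable phenotypes for RF")
            continue
        summary = importance_summary(results)
        summary.to_csv(batch / "rf_summary.csv", index=False, na_rep="NA")
        pd.concat(samples).to_csv(batch / "rf_importance_samples.csv",
                                  index=False, na_rep="NA")
        print(f"{species}:")
        for _, row in summary.iterrows():
            print(f"  {row['metric']:<22s} R2full={row['r2_full']:5.1f} "
                  f"R2red={row['r2_reduced']:5.1f} "
                  f"selected={row['selected']}")


if __name__ == "__main__":
    main()
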