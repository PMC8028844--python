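"""Simulate demonstration batches of bean and maize phenotypes and write
their phene and aggregate-metric tables.

Produces results/batch_<species>/{phenes.csv,metrics.csv}: one phene row
per phenotype x day, and metric rows in three representations (3D,
projection-mean, projection-cv).  Batch sizes are deliberately small so
the whole analysis sequence runs in minutes; raise --n for production.
"""

import argparse

from rootphene.pipeline import RunConfig, run_batch


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=30, help="phenotypes/species")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--end-day", type=float, default=20.0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    days = tuple(d for d in (10, 15, 20, 25, 30, 35, 40)
                 if d <= args.end_day)
    for species in ("bean", "maize"):
        cfg = RunConfig(species=species, n_phenotypes=args.n,
                        seed=args.seed, end_day=args.end_day, days=days,
                        stochastic_cv=0.15,
                        out_dir=f"{args.out}/batch_{species}")
        out = run_batch(cfg, verbose=True)
        print(f"{species}: batch of {args.n} phenotypes written to {out}")


if __name__ == "__main__":
    main()
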