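"""Min-max scale the phene tables, cluster phenotypes hierarchically and
compute Spearman correlation matrices among phenes and aggregate metrics.

Writes, per species: the scaled phene table with the dendrogram leaf
order, the phene x phene and metric x metric Spearman matrices, and a
combined clustered heat-map figure.  The expected structure: axial length
negatively correlated with count/diameter/LRBD classes when a carbon
budget is active, and the hull/width/ellipse-minor block positively
intercorrelated but anticorrelated with solidity.
"""

import argparse
from pathlib import Path

import pandas as pd

from rootphene.analysis import hcluster, scale_minmax, spearman_matrix
from rootphene.pipeline import load_batch


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
        phenes, metrics = load_batch(batch)
        p = phenes[phenes["day"] == args.day].set_index("phenotype")
        p = p.drop(columns=["day", "seed"]).dropna(axis=1, how="all")
        p = p.fillna(0.0).loc[:, p.std() > 0]
        scaled, flagged = scale_minmax(p)
        Z, order = hcluster(scaled)
        scaled.iloc[order].to_csv(batch / "phenes_scaled_clustered.csv")

        rho_p = spearman_matrix(p)
        rho_p.to_csv(batch / "spearman_phenes.csv")
        m = metrics[(metrics["day"] == args.day) &
                    (metrics["representation"] == "3D")]
        m = m.set_index("phenotype").select_dtypes("number")
        m = m.drop(columns=["day"]).dropna(axis=1, how="all")
        m = m.loc[:, m.std() > 0]
        rho_m = spearman_matrix(m)
        rho_m.to_csv(batch / "spearman_metrics.csv")

        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, axes = plt.subplots(1, 2, figsize=(14, 6))
            axes[0].imshow(scaled.iloc[order], aspect="auto", cmap="RdBu_r")
            axes[0].set_title(f"{species}: scaled phenes (clustered)")
            axes[0].set_xticks(range(len(scaled.columns)))
            axes[0].set_xticklabels(scaled.columns, rotation=90, fontsize=5)
            im = axes[1].imshow(rho_m, vmin=-1, vmax=1, cmap="RdBu_r")
            axes[1].set_title("Spearman: aggregate metrics")
            axes[1].set_xticks(range(len(rho_m)))
            axes[1].set_xticklabels(rho_m.columns, rotation=90, fontsize=6)
            axes[1].set_yticks(range(len(rho_m)))
            axes[1].set_yticklabels(rho_m.columns, fontsize=6)
            fig.colorbar(im, ax=axes[1])
            fig.tight_layout()
            fig.savefig(batch / "cluster_heatmap.png", dpi=120)
            plt.close(fig)
        except Exception as e:  # plotting is optional
            print(f"plotting skipped: {e}")

        hw = rho_m.loc["convex_hull_volume", "max_width"] \
            if "max_width" in rho_m else float("nan")
        print(f"{species}: {len(p)} phenotypes clustered; "
              f"rho(hull volume, max width) = {hw:.2f}")


if __name__ == "__main__":
    main()
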