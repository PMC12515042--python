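#!/usr/bin/env python
"""Delineate edaphoclimatic ecoregions: PCA on the scaled environmental
table, sqrt-eigenvalue weighting of the first 5 axes, K-means cascade with
Calinski-Harabasz selection, and per-CWP axis tests.  Reads
results/preprocess/, writes results/ecoregions/."""

import argparse
from pathlib import Path

import pandas as pd

import cwpsoil as cw
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--indir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--outdir", type=Path, default=Path("results/ecoregions"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = cw.RunConfig(seed=args.seed)

    env = io.read_env_table(args.indir / "env_imputed.tsv")
    sites = io.read_site_table(args.datadir / "sites.tsv")

    pca = cw.run_pca(env)
    var_pct = 100 * pca.variance_fraction
    print(f"PC1+PC2 explain {var_pct[0] + var_pct[1]:.0f}% of the variance; "
          f"first {cfg.n_pca_axes} axes {var_pct[:cfg.n_pca_axes].sum():.0f}%")
    for c in range(2):
        top = pca.squared_cosines.iloc[:, c].idxmax()
        print(f"  PC{c + 1} best interpreted by {top} "
              f"(cos2 = {pca.squared_cosines.iloc[:, c].max():.2f})")

    weighted = cw.weight_scores(pca, cfg.n_pca_axes)
    assignment = cw.select_k_calinski(
        weighted, k_range=cfg.kmeans_k_range, n_starts=cfg.kmeans_n_starts,
        seed=cfg.stage_seed("ecoregions"),
    )
    print(f"Calinski-Harabasz selects k = {assignment.k_selected} ecoregions; "
          f"sizes {assignment.labels.value_counts().sort_index().tolist()}")

    truth_path = args.datadir / "truth_ecoregions.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)["ecoregion"]
        acc = cw.matched_accuracy(truth, assignment.labels)
        print(f"agreement with planted ecoregions (optimal matching): {acc:.3f}")

    tests = cw.test_axis_differences(pca.scores.iloc[:, :2], sites)
    n_sig = int(tests["significant"].sum())
    print(f"axis tests: {n_sig}/{len(tests)} CWP x axis medians differ from 0")

    pca.scores.to_csv(args.outdir / "pca_scores.tsv", sep="\t", index_label="site_id")
    pca.loadings.to_csv(args.outdir / "pca_loadings.tsv", sep="\t",
                        index_label="variable")
    pd.DataFrame({"k": list(assignment.ch_values),
                  "calinski_harabasz": list(assignment.ch_values.values())}
                 ).to_csv(args.outdir / "ch_curve.tsv", sep="\t", index=False)
    assignment.labels.to_frame().to_csv(args.outdir / "ecoregions.tsv", sep="\t",
                                        index_label="site_id")
    tests.to_csv(args.outdir / "axis_tests.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
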