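#!/usr/bin/env python
"""Module biogeography: per-population standardized module abundances
(z-scores averaged per module) and module completeness per ecoregion, with
Bonferroni compact-letter comparisons.  Writes results/module_ecology/."""

import argparse
from pathlib import Path

import pandas as pd

import cwpsoil as cw
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--predir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--netdir", type=Path, default=Path("results/networks"))
    ap.add_argument("--ecodir", type=Path, default=Path("results/ecoregions"))
    ap.add_argument("--outdir", type=Path, default=Path("results/module_ecology"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ecoregions = pd.read_csv(args.ecodir / "ecoregions.tsv", sep="\t",
                             index_col=0)["ecoregion"]

    for kingdom in cw.KINGDOMS:
        net_path = args.netdir / f"network_{kingdom}.tsv"
        rare_path = args.predir / f"rarefied_{kingdom}.tsv"
        if not (net_path.exists() and rare_path.exists()):
            continue
        net = io.read_network(net_path)
        rare = io.read_count_table(rare_path)
        core_taxa = [t for t in net.nodes if t in rare.index]

        z = cw.zscore_rows(rare.loc[core_taxa].T)
        mod_ab = cw.module_abundance(z, net.membership)
        mod_ab.to_csv(args.outdir / f"module_abundance_{kingdom}.tsv", sep="\t",
                      index_label="site_id")

        pres = cw.presence_matrix(rare.loc[core_taxa])
        per_pop, summary = cw.module_completeness(
            pres, net.membership, ecoregions, modules=net.main_modules or None
        )
        per_pop.to_csv(args.outdir / f"completeness_{kingdom}.tsv", sep="\t",
                       index=False)
        print(f"{kingdom}: mean completeness by ecoregion x module")
        print(summary.round(2).to_string())

        frames = []
        for eco_label, sub in per_pop.groupby("ecoregion"):
            if sub["module"].nunique() < 2:
                continue
            rep = cw.compare_groups(
                sub["completeness"].reset_index(drop=True),
                sub["module"].reset_index(drop=True),
            )
            rep.insert(0, "ecoregion", eco_label)
            frames.append(rep)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                args.outdir / f"comparisons_{kingdom}.tsv", sep="\t", index=False
            )


if __name__ == "__main__":
    main()
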