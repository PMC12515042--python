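#!/usr/bin/env python
"""Select the per-kingdom soil core community (top 10% by mean relative
abundance, present in >= 4 CWP species) and tabulate cross-CWP overlap.
Reads results/data + results/preprocess, writes results/core/."""

import argparse
from pathlib import Path

import pandas as pd

import cwpsoil as cw
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--indir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--outdir", type=Path, default=Path("results/core"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = cw.RunConfig()

    sites = io.read_site_table(args.datadir / "sites.tsv")
    truth_path = args.datadir / "truth_modules.tsv"
    truth = (pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None)

    summary = []
    for kingdom in cw.KINGDOMS:
        path = args.indir / f"rarefied_{kingdom}.tsv"
        if not path.exists():
            continue
        rare = io.read_count_table(path)
        rel = cw.relative_abundance(rare)
        pres = cw.presence_matrix(rare)
        core = cw.select_core(
            rel, pres, sites, counts=rare,
            top_fraction=cfg.core_top_fraction, min_cwps=cfg.core_min_cwps,
            kingdom=kingdom,
        )
        upset = cw.overlap_counts(core, pres, sites)
        core.stats.to_csv(args.outdir / f"core_{kingdom}.tsv", sep="\t")
        upset.to_csv(args.outdir / f"upset_{kingdom}.tsv", sep="\t", index=False)
        msg = (f"{kingdom}: {len(core.taxa)} core taxa = "
               f"{100 * core.richness_share:.1f}% of richness, "
               f"{100 * core.read_share:.1f}% of reads")
        if truth is not None:
            planted = set(truth.loc[truth.kingdom == kingdom, "taxon"])
            got = set(core.taxa)
            msg += f"; Jaccard vs planted core {len(got & planted) / len(got | planted):.2f}"
        print(msg)
        summary.append({"kingdom": kingdom, "n_core": len(core.taxa),
                        "richness_share": core.richness_share,
                        "read_share": core.read_share})
    pd.DataFrame(summary).to_csv(args.outdir / "core_summary.tsv", sep="\t",
                                 index=False)


if __name__ == "__main__":
    main()
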