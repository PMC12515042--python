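#!/usr/bin/env python
"""Build per-kingdom co-occurrence networks over core phylotypes (exact
hypergeometric co-presence test at P < .05) and detect modules by walktrap.
Reads results/preprocess + results/core, writes results/networks/."""

import argparse
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import cwpsoil as cw
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--predir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--coredir", type=Path, default=Path("results/core"))
    ap.add_argument("--outdir", type=Path, default=Path("results/networks"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = cw.RunConfig(seed=args.seed)

    truth_path = args.datadir / "truth_modules.tsv"
    truth = (pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None)

    rows = []
    for kingdom in cw.KINGDOMS:
        rare_path = args.predir / f"rarefied_{kingdom}.tsv"
        core_path = args.coredir / f"core_{kingdom}.tsv"
        if not (rare_path.exists() and core_path.exists()):
            continue
        rare = io.read_count_table(rare_path)
        core_taxa = pd.read_csv(core_path, sep="\t")["taxon"].astype(str).tolist()
        pres = cw.presence_matrix(rare).loc[core_taxa]
        net = cw.build_network(pres, alpha=cfg.edge_alpha, kingdom=kingdom)
        net = cw.detect_modules(net, steps=cfg.walktrap_steps,
                                seed=cfg.stage_seed("network", kingdom))
        net = cw.main_modules(net, min_size=cfg.main_module_min_size)
        io.write_network(net, args.outdir / f"network_{kingdom}.tsv")
        io.write_network(net, args.outdir / f"network_{kingdom}.graphml", "graphml")
        msg = (f"{kingdom}: {len(net.nodes)} nodes, {net.n_edges} edges, "
               f"{len(net.main_modules)} main modules, Q = {net.modularity:.2f}")
        if truth is not None:
            planted = dict(
                truth.loc[truth.kingdom == kingdom, ["taxon", "module"]].itertuples(
                    index=False, name=None
                )
            )
            common = [t for t in net.membership if t in planted]
            if common:
                ari = adjusted_rand_score([planted[t] for t in common],
                                          [net.membership[t] for t in common])
                msg += f", ARI vs planted modules {ari:.2f}"
        print(msg)
        rows.append({"kingdom": kingdom, "nodes": len(net.nodes),
                     "edges": net.n_edges, "modularity": net.modularity,
                     "n_main_modules": len(net.main_modules)})
    pd.DataFrame(rows).to_csv(args.outdir / "network_summary.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
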