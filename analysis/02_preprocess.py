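#!/usr/bin/env python
"""Impute the environmental table by chained predictive mean matching and
rarefy each kingdom to its reference depth (12000/8000/5000/250 reads).
Reads results/data/, writes results/preprocess/."""

import argparse
from pathlib import Path

import cwpsoil as cw
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cycles", type=int, default=999)
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/preprocess"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = cw.RunConfig(seed=args.seed, imputation_cycles=args.cycles)

    env = io.read_env_table(args.indir / "env.tsv")
    n_missing = int(env.isna().to_numpy().sum())
    done = cw.impute_pmm(env, n_cycles=cfg.imputation_cycles,
                         n_donors=cfg.imputation_donors,
                         seed=cfg.stage_seed("impute"))
    io.write_env_table(done, args.outdir / "env_imputed.tsv")
    print(f"imputed {n_missing} of {env.size} cells "
          f"({100 * n_missing / env.size:.1f}%) in {cfg.imputation_cycles} cycles")

    for kingdom, depth in cfg.rarefaction_depths.items():
        path = args.indir / f"counts_{kingdom}.tsv"
        if not path.exists():
            continue
        counts = io.read_count_table(path)
        rare, dropped = cw.rarefy(counts, depth, seed=cfg.stage_seed("rarefy", kingdom))
        io.write_count_table(rare, args.outdir / f"rarefied_{kingdom}.tsv")
        print(f"{kingdom}: rarefied to {depth} reads, kept {rare.shape[1]} samples, "
              f"dropped {len(dropped)}")


if __name__ == "__main__":
    main()
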