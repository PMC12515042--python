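#!/usr/bin/env python
"""Environmental drivers of module abundances: VIF screen, random-intercept
mixed models (CWP identity), backward-AIC selection, parametric-bootstrap
CIs, and unique/shared variance partitioning over predictor groups.
Writes results/drivers/."""

import argparse
import warnings
from pathlib import Path

import pandas as pd

import cwpsoil as cw
from cwpsoil import drivers
from cwpsoil import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--predir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--moddir", type=Path, default=Path("results/module_ecology"))
    ap.add_argument("--outdir", type=Path, default=Path("results/drivers"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = cw.RunConfig(seed=args.seed, n_bootstrap=args.n_boot)
    warnings.filterwarnings("ignore", message="random-intercept variance")

    sites = io.read_site_table(args.datadir / "sites.tsv")
    env = io.read_env_table(args.predir / "env_imputed.tsv")
    predictors = [c for cols in drivers.PREDICTOR_GROUPS.values()
                  for c in cols if c in env.columns]
    groups_avail = {g: [c for c in cols if c in env.columns]
                    for g, cols in drivers.PREDICTOR_GROUPS.items()}

    for kingdom in cw.KINGDOMS:
        path = args.moddir / f"module_abundance_{kingdom}.tsv"
        if not path.exists():
            continue
        mod_ab = pd.read_csv(path, sep="\t", index_col=0)
        X = drivers.standardize(env.loc[mod_ab.index, predictors])
        retained, vif_report = cw.vif_filter(X, cfg.vif_threshold)
        vif_report.to_csv(args.outdir / f"vif_{kingdom}.tsv", sep="\t", index=False)
        grouping = sites.loc[mod_ab.index, "cwp_species"]

        for mcol in mod_ab.columns:
            response = mod_ab[mcol]
            fit, trace = cw.backward_aic(response, X[retained], grouping)
            ci = cw.bootstrap_ci(fit, n_boot=cfg.n_bootstrap,
                                 seed=cfg.stage_seed(f"bootstrap:{mcol}", kingdom))
            selected = list(fit.fixed.columns)
            part = cw.partition_r2(
                response, X[selected], grouping,
                {g: [c for c in cols if c in selected]
                 for g, cols in groups_avail.items()},
            )
            coef = pd.DataFrame({"estimate": fit.params, "se": fit.se,
                                 "ci_lower": ci["ci_lower"],
                                 "ci_upper": ci["ci_upper"]})
            coef.to_csv(args.outdir / f"coefficients_{kingdom}_{mcol}.tsv",
                        sep="\t", index_label="term")
            trace.to_csv(args.outdir / f"aic_trace_{kingdom}_{mcol}.tsv",
                         sep="\t", index=False)
            part.to_csv(args.outdir / f"partition_{kingdom}_{mcol}.tsv",
                        sep="\t", index=False)
            top = (fit.params.drop("Intercept").abs().sort_values(ascending=False)
                   .head(3).index.tolist())
            print(f"{kingdom} {mcol}: R2m = {fit.r2m:.2f}, R2c = {fit.r2c:.2f}; "
                  f"leading drivers {top}")


if __name__ == "__main__":
    main()
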