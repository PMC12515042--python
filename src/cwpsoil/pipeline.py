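"""End-to-end pipeline: impute -> rarefy -> ecoregions -> core -> network ->
module ecology -> drivers.

``run_pipeline`` takes in-memory tables (or a directory of files via the
CLI), executes every stage with seeds split deterministically from the root
seed, optionally writes all stage outputs as TSV/GraphML under a result
directory, and returns the stage products for programmatic use.  Any sample
id present in a count table but absent from the site table is a hard error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_community, ecoregions, io, module_ecology, network, preprocess
from . import drivers as drv
from .config import RunConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_samples(counts: dict[str, pd.DataFrame], sites: pd.DataFrame) -> None:
    for kingdom, table in counts.items():
        unknown = set(table.columns) - set(sites.index)
        if unknown:
            raise ValueError(
                f"{kingdom}: samples missing from the site table: {sorted(unknown)}"
            )


def run_pipeline(
    config: RunConfig,
    sites: pd.DataFrame,
    env: pd.DataFrame,
    counts: dict[str, pd.DataFrame],
    outdir: str | Path | None = None,
) -> dict:
    """Execute every stage; return all products keyed by stage."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config.to_dict(), "config_hash": config.config_hash()}
    log.info("run: seed=%d config=%s", config.seed, config.config_hash())

    def save_tsv(frame: pd.DataFrame, name: str, **kw) -> None:
        if out is not None:
            frame.to_csv(out / name, sep="\t", **kw)

    try:
        _check_samples(counts, sites)
    except Exception as e:  # noqa: BLE001
        raise StageError("input-validation", e) from e

    # --- impute -----------------------------------------------------------
    try:
        env_complete = preprocess.impute_pmm(
            env,
            n_cycles=config.imputation_cycles,
            n_donors=config.imputation_donors,
            seed=config.stage_seed("impute"),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("impute", e) from e
    results["env"] = env_complete
    save_tsv(env_complete, "env_imputed.tsv", index_label="site_id")
    log.info("impute: %d cells filled", int(env.isna().to_numpy().sum()))

    # --- rarefy -----------------------------------------------------------
    rarefied: dict[str, pd.DataFrame] = {}
    dropped: dict[str, list[str]] = {}
    for kingdom, table in counts.items():
        depth = config.rarefaction_depths.get(kingdom)
        if depth is None:
            raise StageError("rarefy", ValueError(f"no rarefaction depth for {kingdom}"))
        try:
            rarefied[kingdom], dropped[kingdom] = preprocess.rarefy(
                table, depth, seed=config.stage_seed("rarefy", kingdom)
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("rarefy", e) from e
        save_tsv(rarefied[kingdom], f"rarefied_{kingdom}.tsv", index_label="taxon_id")
        log.info(
            "rarefy[%s]: depth=%d kept=%d dropped=%d",
            kingdom, depth, rarefied[kingdom].shape[1], len(dropped[kingdom]),
        )
    results["rarefied"] = rarefied
    results["dropped_samples"] = dropped

    # --- ecoregions -------------------------------------------------------
    try:
        pca = ecoregions.run_pca(env_complete)
        weighted = ecoregions.weight_scores(pca, config.n_pca_axes)
        assignment = ecoregions.select_k_calinski(
            weighted,
            k_range=config.kmeans_k_range,
            n_starts=config.kmeans_n_starts,
            seed=config.stage_seed("ecoregions"),
        )
        axis_tests = ecoregions.test_axis_differences(
            pca.scores.iloc[:, :2], sites, alpha=0.05
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("ecoregions", e) from e
    results.update(pca=pca, weighted_scores=weighted, ecoregions=assignment,
                   axis_tests=axis_tests)
    save_tsv(pca.scores, "pca_scores.tsv", index_label="site_id")
    save_tsv(pca.loadings, "pca_loadings.tsv", index_label="variable")
    save_tsv(
        pd.DataFrame(
            {"k": list(assignment.ch_values),
             "calinski_harabasz": list(assignment.ch_values.values()),
             "within_ss": [assignment.within_ss[k] for k in assignment.ch_values]}
        ),
        "ch_curve.tsv", index=False,
    )
    save_tsv(assignment.labels.to_frame(), "ecoregions.tsv", index_label="site_id")
    save_tsv(axis_tests, "axis_tests.tsv", index=False)
    log.info("ecoregions: k=%d", assignment.k_selected)

    # --- core / network / module ecology / drivers per kingdom ------------
    results["core"] = {}
    results["networks"] = {}
    results["module_abundance"] = {}
    results["completeness"] = {}
    results["comparisons"] = {}
    results["drivers"] = {}
    core_summary_rows = []
    network_summary_rows = []

    predictors_all = [
        c for cols in drv.PREDICTOR_GROUPS.values() for c in cols
        if c in env_complete.columns
    ]
    groups_available = {
        g: [c for c in cols if c in env_complete.columns]
        for g, cols in drv.PREDICTOR_GROUPS.items()
    }

    for kingdom, table in rarefied.items():
        stage = f"core[{kingdom}]"
        try:
            rel = preprocess.relative_abundance(table)
            pres = preprocess.presence_matrix(table)
            core = core_community.select_core(
                rel, pres, sites,
                counts=table,
                top_fraction=config.core_top_fraction,
                min_cwps=config.core_min_cwps,
                kingdom=kingdom,
            )
            upset = core_community.overlap_counts(core, pres, sites)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        results["core"][kingdom] = core
        save_tsv(core.stats, f"core_{kingdom}.tsv")
        save_tsv(upset, f"upset_{kingdom}.tsv", index=False)
        core_summary_rows.append(
            {"kingdom": kingdom, "n_taxa": table.shape[0], "n_core": len(core.taxa),
             "richness_share": core.richness_share, "read_share": core.read_share}
        )
        log.info("%s: %d core taxa", stage, len(core.taxa))

        stage = f"network[{kingdom}]"
        try:
            net = network.build_network(
                pres.loc[core.taxa], alpha=config.edge_alpha, kingdom=kingdom
            )
            net = network.detect_modules(
                net, steps=config.walktrap_steps,
                seed=config.stage_seed("network", kingdom),
            )
            net = network.main_modules(net, min_size=config.main_module_min_size)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        results["networks"][kingdom] = net
        if out is not None:
            io.write_network(net, out / f"network_{kingdom}.tsv", "edge-list-tsv")
            io.write_network(net, out / f"network_{kingdom}.graphml", "graphml")
        modules_frame = pd.DataFrame(
            {"taxon": list(net.membership),
             "module": list(net.membership.values())}
        )
        modules_frame["main"] = modules_frame["module"].isin(net.main_modules)
        save_tsv(modules_frame, f"modules_{kingdom}.tsv", index=False)
        network_summary_rows.append(
            {"kingdom": kingdom, "nodes": len(net.nodes), "edges": net.n_edges,
             "modularity": net.modularity,
             "n_modules": len(set(net.membership.values())),
             "n_main_modules": len(net.main_modules)}
        )
        log.info("%s: %d edges, %d main modules", stage, net.n_edges,
                 len(net.main_modules))

        stage = f"modules[{kingdom}]"
        try:
            x = table.loc[core.taxa].T  # populations x core taxa
            z = module_ecology.zscore_rows(x)
            mod_ab = module_ecology.module_abundance(z, net.membership)
            eco_labels = assignment.labels
            per_pop, summary = module_ecology.module_completeness(
                pres.loc[core.taxa], net.membership, eco_labels,
                modules=net.main_modules or None,
            )
            comparisons = []
            for eco_label, sub in per_pop.groupby("ecoregion"):
                if sub["module"].nunique() < 2 or (sub["module"].value_counts() < 2).any():
                    continue
                rep = module_ecology.compare_groups(
                    sub.set_index("population", append=False)["completeness"].reset_index(drop=True),
                    sub["module"].reset_index(drop=True),
                )
                rep.insert(0, "ecoregion", eco_label)
                comparisons.append(rep)
            comparisons = (
                pd.concat(comparisons, ignore_index=True)
                if comparisons else pd.DataFrame()
            )
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        results["module_abundance"][kingdom] = mod_ab
        results["completeness"][kingdom] = (per_pop, summary)
        results["comparisons"][kingdom] = comparisons
        save_tsv(mod_ab, f"module_abundance_{kingdom}.tsv", index_label="site_id")
        save_tsv(per_pop, f"completeness_{kingdom}.tsv", index=False)
        save_tsv(comparisons, f"comparisons_{kingdom}.tsv", index=False)

        stage = f"drivers[{kingdom}]"
        try:
            X_full = drv.standardize(env_complete.loc[x.index, predictors_all])
            retained, vif_report = drv.vif_filter(X_full, config.vif_threshold)
            save_tsv(vif_report, f"vif_{kingdom}.tsv", index=False)
            grouping = sites.loc[x.index, "cwp_species"]
            kingdom_fits = {}
            for mcol in mod_ab.columns:
                m = int(mcol.split("_")[1])
                if net.main_modules and m not in net.main_modules:
                    continue
                response = mod_ab[mcol]
                fit, trace = drv.backward_aic(response, X_full[retained], grouping)
                ci = drv.bootstrap_ci(
                    fit, n_boot=config.n_bootstrap,
                    seed=config.stage_seed(f"bootstrap:{mcol}", kingdom),
                )
                selected = list(fit.fixed.columns)
                part = drv.partition_r2(
                    response, X_full[selected], grouping,
                    {g: [c for c in cols if c in selected]
                     for g, cols in groups_available.items()},
                )
                try:
                    ad_stat, ad_p = drv.residual_normality(fit)
                except ValueError:
                    ad_stat, ad_p = np.nan, np.nan
                coef = pd.DataFrame(
                    {"estimate": fit.params, "se": fit.se,
                     "ci_lower": ci["ci_lower"], "ci_upper": ci["ci_upper"]}
                )
                wald_p = 2 * (1 - _norm_cdf(np.abs(coef["estimate"] / coef["se"])))
                coef["stars"] = [drv.significance_stars(p) for p in wald_p]
                kingdom_fits[m] = {
                    "fit": fit, "trace": trace, "ci": ci, "partition": part,
                    "anderson_darling": (ad_stat, ad_p),
                }
                save_tsv(coef, f"drivers_coefficients_{kingdom}_module{m}.tsv",
                         index_label="term")
                save_tsv(trace, f"aic_trace_{kingdom}_module{m}.tsv", index=False)
                part_out = part.copy()
                part_out["r2m_full"] = part.attrs["r2m_full"]
                part_out["random_fraction"] = part.attrs["random_fraction"]
                part_out["residual_fraction"] = part.attrs["residual_fraction"]
                save_tsv(part_out, f"drivers_partition_{kingdom}_module{m}.tsv",
                         index=False)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        results["drivers"][kingdom] = kingdom_fits
        log.info("%s: %d module models", stage, len(kingdom_fits))

    save_tsv(pd.DataFrame(core_summary_rows), "core_summary.tsv", index=False)
    save_tsv(pd.DataFrame(network_summary_rows), "network_summary.tsv", index=False)
    if out is not None:
        (out / "run_info.json").write_text(
            json.dumps(
                {"seed": config.seed, "config_hash": config.config_hash(),
                 "config": config.to_dict(),
                 "stages": {
                     "core": core_summary_rows,
                     "network": network_summary_rows,
                 }},
                indent=2, default=str,
            )
        )
    return results


def _norm_cdf(x):
    from scipy.stats import norm

    return norm.cdf(x)
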