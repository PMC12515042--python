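"""Biogeography of co-occurrence modules.

Reads of core phylotypes are standardized within each wild population
(z_ij = (x_ij - mean_i) / sd_i over taxa j in population i) so every
phylotype contributes on a common scale regardless of module size; the
standardized values are averaged per module and population, and module
completeness (fraction of a module's nodes present in a population) is
aggregated by ecoregion.  Differences across groups are assessed with
one-way linear models, Bonferroni-adjusted pairwise comparisons, and
compact letters.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .stats import compact_letter_display, pairwise_bonferroni

log = logging.getLogger(__name__)


def zscore_rows(x: pd.DataFrame, per_taxon: bool = False) -> pd.DataFrame:
    """Standardize reads within each population (matrix rows = sites).

    Default: z_ij = (x_ij - mean_i) / sd_i with the mean and sample standard
    deviation (denominator n-1) taken over taxa within site i.  Rows with
    zero spread yield all-zero z (with a warning).  ``per_taxon=True``
    standardizes each taxon across sites instead (the alternative reading of
    "balanced contribution of the phylotypes").
    """
    if per_taxon:
        return zscore_rows(x.T, per_taxon=False).T
    if x.shape[1] < 2:
        raise ValueError("row standardization needs at least 2 taxa")
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant rows standardized to all-zero z",
            stacklevel=2,
        )
    safe_sd = sd.replace(0, 1.0)
    return x.sub(mu, axis=0).div(safe_sd, axis=0)


def module_abundance(z: pd.DataFrame, membership: dict[str, int]) -> pd.DataFrame:
    """Mean standardized abundance per site and module.

    Entry (i, m) is the mean of z_ij over taxa j in module m.  Modules with
    no taxa in z produce an all-NA column.
    """
    modules = sorted(set(membership.values()))
    out = {}
    for m in modules:
        taxa = [t for t in z.columns if membership.get(t) == m]
        if not taxa:
            out[m] = np.full(len(z), np.nan)
        else:
            out[m] = z[taxa].mean(axis=1).to_numpy()
    df = pd.DataFrame(out, index=z.index)
    df.columns = [f"module_{m}" for m in modules]
    return df


def module_completeness(
    presence: pd.DataFrame,
    membership: dict[str, int],
    ecoregions: pd.Series,
    modules: set[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module completeness per population, summarized per ecoregion.

    completeness(p, m) = fraction of module m's nodes present in population
    p.  Returns (per-population records, ecoregion x module mean table).
    ``modules`` restricts the computation (e.g. to main modules); empty
    modules are excluded with a warning.
    """
    if not set(ecoregions.index) >= set(presence.columns):
        raise ValueError("every population needs an ecoregion label")
    module_taxa: dict[int, list[str]] = {}
    for t, m in membership.items():
        if modules is not None and m not in modules:
            continue
        module_taxa.setdefault(m, []).append(t)
    records = []
    for m, taxa in sorted(module_taxa.items()):
        taxa = [t for t in taxa if t in presence.index]
        if not taxa:
            warnings.warn(f"module {m} has no taxa in the presence table; excluded")
            continue
        frac = presence.loc[taxa].mean(axis=0)
        for pop, value in frac.items():
            records.append(
                {
                    "population": pop,
                    "module": m,
                    "completeness": float(value),
                    "ecoregion": ecoregions[pop],
                }
            )
    per_pop = pd.DataFrame(records)
    summary = (
        per_pop.pivot_table(
            index="ecoregion", columns="module", values="completeness", aggfunc="mean"
        )
        if len(per_pop)
        else pd.DataFrame()
    )
    return per_pop, summary


def compare_groups(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way linear model with Bonferroni pairwise comparisons and letters.

    Groups with a single observation are excluded (with a warning).  Output:
    one row per retained group with n, mean, and compact letter; groups
    sharing a letter do not differ significantly at ``alpha``.
    """
    values, groups = values.align(groups, join="inner")
    counts = groups.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups excluded with < 2 observations: {singletons}")
        keep = ~groups.isin(singletons)
        values, groups = values[keep], groups[keep]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    pw = pairwise_bonferroni(values.to_numpy(), groups.to_numpy())
    letters = compact_letter_display(list(groups.unique()), pw, alpha=alpha)
    out = (
        values.groupby(groups)
        .agg(["size", "mean"])
        .rename(columns={"size": "n", "mean": "mean"})
        .reset_index()
        .rename(columns={groups.name or "index": "group"})
    )
    out.columns = ["group", "n", "mean"]
    out["letter"] = out["group"].map(letters)
    return out
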